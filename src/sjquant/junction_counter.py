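"""Count spliced reads supporting discriminating junctions in SAM/BAM files.

Spliced alignments encode introns as skipped-region (``N``) CIGAR
operations.  A read supports a junction when an ``N`` operation lands
exactly on the junction's genomic coordinates and the read contributes
enough aligned reference bases (*anchor*) on both sides — short anchors are
unreliable evidence of the splice.  Counting is done under stringent,
configurable filters: exact coordinate match, minimum anchor length on each
side (default 8 nt, mirroring the 8-base junction-overlap rule used for
junction-spanning qPCR primers), primary non-duplicate records only, and an
optional mapping-quality floor.

The denominators needed for normalization are collected in the same pass:
``total_reads`` (records passing the record-level filters, spliced or not)
and ``gene_reads`` (the subset overlapping the gene's genomic span).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Union

import pysam

from .gene_models import DiscriminatingJunctionMap, GeneModel, Junction

__all__ = [
    "FilterConfig",
    "JunctionCountTable",
    "extract_read_junctions",
    "anchor_lengths",
    "passes_filters",
    "count_junctions",
    "write_counts_tsv",
]

log = logging.getLogger(__name__)

# CIGAR op codes (pysam numeric encoding)
_MATCH_OPS = {0, 7, 8}  # M, =, X
_REF_OPS = {0, 2, 3, 7, 8}  # reference-consuming: M, D, N, =, X
_SKIP = 3  # N


@dataclass(frozen=True)
class FilterConfig:
    """Read- and junction-level filters applied during counting.

    min_anchor : minimum aligned reference bases flanking the junction on
        each side, inclusive ("at least" semantics); default 8 nt.
    min_mapq : minimum mapping quality; default 0.
    primary_only / exclude_duplicates / exclude_secondary_supplementary :
        record-level flag filters, all on by default.
    """

    min_anchor: int = 8
    min_mapq: int = 0
    primary_only: bool = True
    exclude_duplicates: bool = True
    exclude_secondary_supplementary: bool = True

    def __post_init__(self) -> None:
        if self.min_anchor < 1:
            raise ValueError("min_anchor must be >= 1")
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")


@dataclass
class JunctionCountTable:
    """Per-sample spliced-read counts plus normalization denominators."""

    sample_id: str
    counts: dict[Junction, int]
    total_reads: int
    gene_reads: int
    filter_config: FilterConfig

    def __post_init__(self) -> None:
        if self.gene_reads > self.total_reads:
            raise ValueError("gene_reads cannot exceed total_reads")
        for j, c in self.counts.items():
            if c < 0 or c > self.total_reads:
                raise ValueError(f"count for {j} outside [0, total_reads]")


def extract_read_junctions(record: pysam.AlignedSegment) -> list[Junction]:
    """Junctions spanned by one alignment record, from its CIGAR N operations.

    For each skip, ``donor_end`` is the last reference base consumed before
    it and ``acceptor_start`` the first base after, 1-based.  Unmapped
    records yield an empty list.
    """
    if record.is_unmapped or record.cigartuples is None:
        return []
    junctions: list[Junction] = []
    chrom = record.reference_name
    pos0 = record.reference_start  # 0-based
    for op, length in record.cigartuples:
        if op == _SKIP:
            # last consumed base is pos0 (1-based), first after skip is pos0+length+1
            junctions.append(Junction(chrom, pos0, pos0 + length + 1))
        if op in _REF_OPS:
            pos0 += length
    return junctions


def anchor_lengths(record: pysam.AlignedSegment, junction: Junction) -> tuple[int, int]:
    """Aligned reference bases immediately flanking ``junction`` in this read.

    Each anchor is the run of reference-consuming, non-skip operations
    between the junction and the nearest adjacent skip (or the alignment
    end).  Soft clips never contribute.  Raises ``ValueError`` if the read
    does not span the junction.
    """
    if record.is_unmapped or record.cigartuples is None:
        raise ValueError("junction not spanned by read")
    # segment lengths between skips, in reference space
    segments: list[int] = [0]
    skips: list[Junction] = []
    pos0 = record.reference_start
    chrom = record.reference_name
    for op, length in record.cigartuples:
        if op == _SKIP:
            skips.append(Junction(chrom, pos0, pos0 + length + 1))
            segments.append(0)
        elif op in _REF_OPS:
            segments[-1] += length
        if op in _REF_OPS:
            pos0 += length
    for i, j in enumerate(skips):
        if j == junction:
            return segments[i], segments[i + 1]
    raise ValueError("junction not spanned by read")


def _record_passes(record: pysam.AlignedSegment, cfg: FilterConfig) -> bool:
    if record.is_unmapped:
        return False
    if cfg.exclude_secondary_supplementary and (record.is_secondary or record.is_supplementary):
        return False
    if cfg.primary_only and record.is_secondary:
        return False
    if cfg.exclude_duplicates and record.is_duplicate:
        return False
    if record.mapping_quality < cfg.min_mapq:
        return False
    return True


def passes_filters(
    record: pysam.AlignedSegment, junction: Junction, cfg: FilterConfig
) -> bool:
    """True iff the record and its support for ``junction`` survive all filters."""
    if not _record_passes(record, cfg):
        return False
    try:
        left, right = anchor_lengths(record, junction)
    except ValueError:
        return False
    return left >= cfg.min_anchor and right >= cfg.min_anchor


AlignmentSource = Union[str, Iterable[pysam.AlignedSegment]]


def _iter_records(alignments: AlignmentSource) -> Iterator[pysam.AlignedSegment]:
    if isinstance(alignments, str):
        try:
            with pysam.AlignmentFile(alignments, check_sq=False) as fh:
                yield from fh
        except (OSError, ValueError) as exc:
            raise ValueError(f"alignment input error: {exc}") from exc
    else:
        yield from alignments


def count_junctions(
    alignments: AlignmentSource,
    catalogue: DiscriminatingJunctionMap,
    gene: GeneModel | None = None,
    cfg: FilterConfig | None = None,
    sample_id: str = "sample",
) -> JunctionCountTable:
    """Count filtered spliced reads over every catalogue junction in one pass.

    ``alignments`` is a SAM/BAM path or an iterable of alignment records
    (the whole stream is walked; with a path, total_reads comes from the
    stream itself, never from index statistics, so SAM and BAM agree).

    A read spanning k catalogue junctions adds 1 to each of the k counts
    but only 1 to ``total_reads``; total_reads counts every record passing
    the record-level filters regardless of splicing, and ``gene_reads`` the
    subset overlapping the gene span (0 when no gene model is given).
    """
    cfg = cfg or FilterConfig()
    wanted = {j: 0 for j in catalogue.all_junctions()}
    total = 0
    gene_hits = 0
    span = (gene.chrom, gene.start, gene.end) if gene is not None else None
    for record in _iter_records(alignments):
        if not _record_passes(record, cfg):
            continue
        total += 1
        if span is not None and record.reference_name == span[0]:
            # reference_start/end are 0-based half-open
            if record.reference_start < span[2] and record.reference_end > span[1] - 1:
                gene_hits += 1
        for junction in extract_read_junctions(record):
            if junction in wanted:
                left, right = anchor_lengths(record, junction)
                if left >= cfg.min_anchor and right >= cfg.min_anchor:
                    wanted[junction] += 1
    log.info(
        "counted %s: total_reads=%d gene_reads=%d junctions=%d",
        sample_id, total, gene_hits, len(wanted),
    )
    return JunctionCountTable(
        sample_id=sample_id,
        counts=wanted,
        total_reads=total,
        gene_reads=gene_hits,
        filter_config=cfg,
    )


def write_counts_tsv(
    tables: Iterable[JunctionCountTable],
    catalogue: DiscriminatingJunctionMap,
    path: str,
) -> None:
    """Write per-sample junction counts as TSV.

    Columns: sample_id, variant_name, chrom, donor_end, acceptor_start,
    spliced_reads, total_reads, gene_reads.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            [
                "sample_id", "variant_name", "chrom", "donor_end",
                "acceptor_start", "spliced_reads", "total_reads", "gene_reads",
            ]
        )
        for table in tables:
            for variant, juncs in sorted(catalogue.by_variant.items()):
                for j in sorted(juncs):
                    w.writerow(
                        [
                            table.sample_id, variant, j.chrom, j.donor_end,
                            j.acceptor_start, table.counts.get(j, 0),
                            table.total_reads, table.gene_reads,
                        ]
                    )
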