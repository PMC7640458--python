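"""Spliced-alignment simulator with per-junction ground truth.

Generates toy multi-isoform genes (a canonical transcript plus
exon-skipping variants, the topology that creates discriminating
junctions), a random contig carrying them, and already-aligned SAM records
whose CIGARs encode the intended splices — with a TruthSet recording every
assignment so each pipeline stage can be tested against known values.

Reads are emitted as alignments directly (no FASTQ or aligner step): the
counting pipeline consumes SAM/BAM, so simulating alignments keeps ground
truth exact and the whole exercise deterministic under a seed.  The
simulated regime mirrors deeply sequenced short-read RNA-seq in ratio, not
volume: single-end 100 nt reads by default (configurable), 10^5 reads per
library standing in for ~2×10^8-read production libraries, per-junction
read probabilities down to the 10^-3 scale, and a minus-strand gene by
default.  Each read is assigned to junction j with probability p_j
(anchors drawn uniformly in the feasible range), placed as an unspliced
read inside the gene span, or placed as unspliced background elsewhere on
the contig.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pysam

from .gene_models import (
    Exon,
    GeneModel,
    Junction,
    Transcript,
    derive_junctions,
    discriminating_junctions,
)

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "make_toy_gene",
    "simulate_reads",
    "write_alignments",
    "write_gtf",
    "write_fasta",
    "simulate_sample",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated library over one toy gene.

    ``variants`` maps variant name -> genomic exon numbers (1-based, in
    genomic order) skipped relative to the canonical; ``junction_probs``
    maps variant name -> per-read probability that a read spans that
    variant's discriminating junction.  ``gene_unspliced_fraction`` is the
    probability a read is an unspliced read inside the gene span; all
    remaining probability becomes unspliced background on the contig.
    Anchor lengths of spliced reads are drawn uniformly from
    [anchor_min, anchor_max] (left side; the right anchor is the read
    remainder), clipped to what the flanking exons allow.
    """

    n_exons: int = 4
    exon_length: tuple[int, int] = (120, 300)
    intron_length: tuple[int, int] = (200, 1500)
    variants: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: {"VAR-skip3": (3,)}
    )
    junction_probs: dict[str, float] = field(
        default_factory=lambda: {"VAR-skip3": 0.007}
    )
    n_reads: int = 100_000
    read_length: int = 100
    strand: str = "-"
    gene_unspliced_fraction: float = 0.02
    anchor_min: int = 1
    anchor_max: int | None = None
    mapq: int = 60
    chrom: str = "chrT"
    margin: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_exons < 1:
            raise ValueError("need at least one exon")
        if self.read_length < 2:
            raise ValueError("read length too short")
        total_p = sum(self.junction_probs.values()) + self.gene_unspliced_fraction
        if total_p > 1.0 + 1e-12:
            raise ValueError("junction probabilities + gene fraction exceed 1")
        for name, skipped in self.variants.items():
            for rank in skipped:
                if not 1 <= rank <= self.n_exons:
                    raise ValueError(f"invalid variant spec: {name} skips exon {rank}")
                if rank in (1, self.n_exons):
                    raise ValueError(
                        f"invalid variant spec: {name} cannot skip a terminal exon"
                    )


@dataclass
class TruthSet:
    """Ground truth of one simulated library.

    ``intended`` is the expected count n_reads·p_j per junction;
    ``realized`` the actual number of emitted reads spanning it;
    ``assignments`` one entry per read (qname, variant name or None).
    """

    intended: dict[Junction, float]
    realized: dict[Junction, int]
    assignments: list[tuple[str, str | None]]
    n_reads: int
    seed: int

    def __post_init__(self) -> None:
        spliced = sum(1 for _, v in self.assignments if v is not None)
        if spliced != sum(self.realized.values()):
            raise ValueError("inconsistent truth set")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, stream)))


def make_toy_gene(cfg: SimulationConfig) -> tuple[GeneModel, str]:
    """Build the toy gene model and its contig sequence, deterministically.

    The canonical transcript has ``n_exons`` exons; each requested variant
    drops the listed exons (creating an exon-skip junction).  The contig is
    random A/C/G/T covering the gene plus ``margin`` on both sides.
    """
    rng = _rng(cfg.seed, 0)
    lo, hi = cfg.exon_length
    ilo, ihi = cfg.intron_length
    exon_lens = rng.integers(lo, hi + 1, size=cfg.n_exons)
    intron_lens = rng.integers(ilo, ihi + 1, size=max(cfg.n_exons - 1, 1))

    bounds: list[tuple[int, int]] = []  # genomic order, 1-based inclusive
    pos = cfg.margin + 1
    for i in range(cfg.n_exons):
        bounds.append((pos, pos + int(exon_lens[i]) - 1))
        pos = bounds[-1][1] + 1
        if i < cfg.n_exons - 1:
            pos += int(intron_lens[i])
    gene_end = bounds[-1][1]
    contig_len = gene_end + cfg.margin
    contig = rng.choice(_BASES, size=contig_len).tobytes().decode()

    def _exons(keep: Sequence[int]) -> list[Exon]:
        n = len(keep)
        out = []
        for i, g in enumerate(keep):  # i in genomic order
            rank = i + 1 if cfg.strand != "-" else n - i
            s, e = bounds[g - 1]
            out.append(Exon(chrom=cfg.chrom, start=s, end=e, transcript_rank=rank))
        return out

    transcripts = [
        Transcript(
            transcript_id="TX-canonical",
            variant_name="CANONICAL",
            biotype="protein_coding",
            strand=cfg.strand,
            exons=_exons(range(1, cfg.n_exons + 1)),
        )
    ]
    for name, skipped in cfg.variants.items():
        keep = [g for g in range(1, cfg.n_exons + 1) if g not in skipped]
        transcripts.append(
            Transcript(
                transcript_id=f"TX-{name}",
                variant_name=name,
                biotype="protein_coding",
                strand=cfg.strand,
                exons=_exons(keep),
            )
        )
    gene = GeneModel(
        gene_id="GENE-toy",
        chrom=cfg.chrom,
        strand=cfg.strand,
        canonical_id="TX-canonical",
        transcripts=transcripts,
    )
    return gene, contig


def _variant_junctions(gene: GeneModel, cfg: SimulationConfig) -> dict[str, Junction]:
    """One discriminating junction per variant named in junction_probs."""
    dmap = discriminating_junctions(gene)
    chosen: dict[str, Junction] = {}
    for name in cfg.junction_probs:
        juncs = dmap.by_variant.get(name)
        if not juncs:
            raise ValueError(f"invalid variant spec: {name} has no discriminating junction")
        chosen[name] = min(juncs)  # deterministic pick
    return chosen


def _exon_ends_around(gene: GeneModel, junction: Junction) -> tuple[int, int]:
    """(left exon length available, right exon length available) at a junction."""
    for t in gene.transcripts:
        exons = sorted(t.exons, key=lambda e: e.start)
        for left, right in zip(exons, exons[1:]):
            if (
                left.chrom == junction.chrom
                and left.end == junction.donor_end
                and right.start == junction.acceptor_start
            ):
                return left.length, right.length
    raise ValueError("junction not in gene")


def simulate_reads(
    gene: GeneModel, contig: str, cfg: SimulationConfig
) -> tuple[list[pysam.AlignedSegment], TruthSet]:
    """Emit aligned reads over the toy gene with known junction assignments.

    Every record carries a correct POS, CIGAR (M/N only), FLAG (strand
    drawn 50/50 — reverse-strand alignments keep identical coordinates,
    exercising the minus-strand gene), MAPQ and reference-matching SEQ.
    """
    rng = _rng(cfg.seed, 1)
    L = cfg.read_length
    junctions = _variant_junctions(gene, cfg)
    names = list(junctions)
    probs = np.array([cfg.junction_probs[n] for n in names], dtype=float)
    edges = np.concatenate([[0.0], np.cumsum(probs)])
    gene_hi = edges[-1] + cfg.gene_unspliced_fraction

    feas: dict[str, tuple[int, int]] = {}
    for n in names:
        left_len, right_len = _exon_ends_around(gene, junctions[n])
        a_lo = max(cfg.anchor_min, L - right_len, 1)
        a_hi = min(cfg.anchor_max if cfg.anchor_max is not None else L - 1, L - 1, left_len)
        if a_lo > a_hi:
            raise ValueError("read length too short for feasible anchors")
        feas[n] = (a_lo, a_hi)

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": cfg.chrom, "LN": len(contig)}],
        }
    )

    u = rng.random(cfg.n_reads)
    flags = rng.integers(0, 2, size=cfg.n_reads) * 16
    records: list[pysam.AlignedSegment] = []
    assignments: list[tuple[str, str | None]] = []
    realized: dict[Junction, int] = {j: 0 for j in junctions.values()}

    gene_start, gene_end = gene.start, gene.end
    contig_len = len(contig)
    for i in range(cfg.n_reads):
        qname = f"r{i:07d}"
        variant: str | None = None
        if u[i] < edges[-1]:
            k = int(np.searchsorted(edges, u[i], side="right")) - 1
            variant = names[k]
            junction = junctions[variant]
            a_lo, a_hi = feas[variant]
            a = int(rng.integers(a_lo, a_hi + 1))
            b = L - a
            pos1 = junction.donor_end - a + 1  # 1-based leftmost
            intron = junction.intron_length
            cigar = [(0, a), (3, intron), (0, b)]
            seq = (
                contig[pos1 - 1 : pos1 - 1 + a]
                + contig[junction.acceptor_start - 1 : junction.acceptor_start - 1 + b]
            )
            realized[junction] += 1
        elif u[i] < gene_hi:
            pos1 = int(rng.integers(gene_start, max(gene_end - L + 2, gene_start + 1)))
            cigar = [(0, L)]
            seq = contig[pos1 - 1 : pos1 - 1 + L]
        else:
            pos1 = int(rng.integers(1, contig_len - L + 2))
            cigar = [(0, L)]
            seq = contig[pos1 - 1 : pos1 - 1 + L]

        rec = pysam.AlignedSegment(header)
        rec.query_name = qname
        rec.flag = int(flags[i])
        rec.reference_id = 0
        rec.reference_start = pos1 - 1
        rec.mapping_quality = cfg.mapq
        rec.cigartuples = cigar
        rec.query_sequence = seq
        rec.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
        records.append(rec)
        assignments.append((qname, variant))

    intended = {
        junctions[n]: cfg.n_reads * cfg.junction_probs[n] for n in names
    }
    truth = TruthSet(
        intended=intended,
        realized=realized,
        assignments=assignments,
        n_reads=cfg.n_reads,
        seed=cfg.seed,
    )
    return records, truth


def write_alignments(
    records: Sequence[pysam.AlignedSegment],
    header: pysam.AlignmentHeader | dict,
    path: str,
) -> None:
    """Write records coordinate-sorted as SAM (or BAM when path ends .bam)."""
    if isinstance(header, dict):
        header = pysam.AlignmentHeader.from_dict(header)
    hd = header.to_dict()
    lengths = {sq["SN"]: sq["LN"] for sq in hd.get("SQ", [])}
    for rec in records:
        ln = lengths.get(rec.reference_name)
        if ln is not None and rec.reference_end is not None and rec.reference_end > ln:
            raise ValueError(f"record out of bounds: {rec.query_name}")
    hd.setdefault("HD", {})["SO"] = "coordinate"
    header = pysam.AlignmentHeader.from_dict(hd)
    mode = "wb" if path.endswith(".bam") else "w"
    ordered = sorted(records, key=lambda r: (r.reference_id, r.reference_start))
    with pysam.AlignmentFile(path, mode, header=header) as out:
        for rec in ordered:
            out.write(rec)


def write_gtf(gene: GeneModel, path: str) -> None:
    """Write the toy gene as GTF, re-parseable by gene_models."""
    with open(path, "w") as fh:
        for t in gene.transcripts:
            attrs = (
                f'gene_id "{gene.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'transcript_name "{t.variant_name}"; transcript_biotype "{t.biotype}";'
            )
            fh.write(
                "\t".join(
                    [gene.chrom, "sjquant_sim", "transcript", str(t.start), str(t.end),
                     ".", t.strand, ".", attrs]
                )
                + "\n"
            )
            for exon in sorted(t.exons, key=lambda e: e.start):
                fh.write(
                    "\t".join(
                        [gene.chrom, "sjquant_sim", "exon", str(exon.start), str(exon.end),
                         ".", t.strand, ".", attrs]
                    )
                    + "\n"
                )


def write_fasta(contigs: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_truth_tsv(truth: TruthSet, path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["chrom", "donor_end", "acceptor_start", "intended", "realized", "seed"])
        for j in sorted(truth.realized):
            w.writerow(
                [j.chrom, j.donor_end, j.acceptor_start,
                 truth.intended.get(j, 0.0), truth.realized[j], truth.seed]
            )


def synthetic_pcr_template(
    fwd: str, rvs: str, amplicon_length: int, seed: int = 0, pad: int = 60
) -> str:
    """Synthetic amplification template for one primer pair.

    A synthetic stand-in for a real transcript sequence: the forward primer
    site and the reverse primer's reverse-complement site are embedded in
    random sequence, spaced so the true amplicon is exactly
    ``amplicon_length`` bp, with ``pad`` random bases on each flank.  The
    construction retries seeds until neither primer has a second accidental
    match, so in-silico PCR on the result is unambiguous.  It exercises
    primer-matching and coordinate arithmetic only — it is not the real
    transcript and carries no biological sequence content.
    """
    from Bio.Seq import reverse_complement as _rc

    interior = amplicon_length - len(fwd) - len(rvs)
    if interior < 0:
        raise ValueError("amplicon shorter than the two primers")
    rvs_site = _rc(rvs.upper())
    for attempt in range(100):
        rng = _rng(seed, 100 + attempt)
        filler = rng.choice(_BASES, size=interior).tobytes().decode()
        left = rng.choice(_BASES, size=pad).tobytes().decode()
        right = rng.choice(_BASES, size=pad).tobytes().decode()
        template = left + fwd.upper() + filler + rvs_site + right
        if template.count(fwd.upper()) == 1 and template.count(rvs_site) == 1:
            return template
    raise RuntimeError("could not build an unambiguous template")


def simulate_sample(
    cfg: SimulationConfig, out_dir: str | None = None, sample_id: str = "sim"
) -> tuple[GeneModel, str, list[pysam.AlignedSegment], TruthSet]:
    """Convenience wrapper: gene + contig + reads (+ files when out_dir given)."""
    gene, contig = make_toy_gene(cfg)
    records, truth = simulate_reads(gene, contig, cfg)
    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        write_gtf(gene, os.path.join(out_dir, f"{sample_id}.gtf"))
        write_fasta({cfg.chrom: contig}, os.path.join(out_dir, f"{sample_id}.fa"))
        if records:
            write_alignments(records, records[0].header, os.path.join(out_dir, f"{sample_id}.sam"))
        else:
            header = pysam.AlignmentHeader.from_dict(
                {"HD": {"VN": "1.6", "SO": "coordinate"},
                 "SQ": [{"SN": cfg.chrom, "LN": len(contig)}]}
            )
            write_alignments([], header, os.path.join(out_dir, f"{sample_id}.sam"))
        write_truth_tsv(truth, os.path.join(out_dir, f"{sample_id}.truth.tsv"))
    return gene, contig, records, truth
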