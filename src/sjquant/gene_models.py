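"""Gene models, splice junctions, and isoform-discriminating junction sets.

A splice junction is the genomic coordinate pair left behind when an intron
is excised: the last base of the genomically-left exon (``donor_end``) and
the first base of the genomically-right exon (``acceptor_start``), both
1-based inclusive.  A junction present in exactly one transcript of a gene
*discriminates* that splice variant: every read spanning it is attributable
to that variant alone.  This module parses a gene's transcript structures
out of a GTF/GFF3 annotation, derives per-transcript junctions, and computes
the discriminating set for each variant.

Coordinates are 1-based inclusive throughout, matching GTF.  Junction
identity is strand-agnostic (keyed on chrom/donor_end/acceptor_start):
counting happens in genomic space, while exon *ranks* follow transcript
orientation, so for a minus-strand gene rank 1 is the genomically rightmost
exon.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio.Seq import reverse_complement

__all__ = [
    "Exon",
    "Transcript",
    "GeneModel",
    "Junction",
    "DiscriminatingJunctionMap",
    "parse_gene_models",
    "derive_junctions",
    "discriminating_junctions",
    "spliced_sequence",
    "write_junction_catalogue",
]


@dataclass(frozen=True, order=True)
class Junction:
    """A splice junction: the exonic bases flanking an excised intron.

    ``donor_end`` is the last base of the genomically-left exon and
    ``acceptor_start`` the first base of the genomically-right exon, both
    1-based inclusive.  Identity is strand-agnostic.
    """

    chrom: str
    donor_end: int
    acceptor_start: int

    def __post_init__(self) -> None:
        if self.acceptor_start < self.donor_end + 2:
            raise ValueError(
                f"invalid junction: intron length < 1 "
                f"({self.chrom}:{self.donor_end}-{self.acceptor_start})"
            )

    @property
    def intron_length(self) -> int:
        return self.acceptor_start - self.donor_end - 1


@dataclass(frozen=True)
class Exon:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    transcript_rank: int  # 1 = first exon in transcript orientation

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"malformed annotation: exon end < start ({self.start}-{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Transcript:
    transcript_id: str
    variant_name: str
    biotype: str
    strand: str
    exons: list[Exon]  # sorted genomically (ascending start)
    cds_start: int | None = None
    cds_end: int | None = None

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def start(self) -> int:
        return min(e.start for e in self.exons)

    @property
    def end(self) -> int:
        return max(e.end for e in self.exons)


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    canonical_id: str
    transcripts: list[Transcript]

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)

    @property
    def canonical(self) -> Transcript:
        for t in self.transcripts:
            if t.transcript_id == self.canonical_id:
                return t
        raise ValueError(f"canonical transcript not found: {self.canonical_id}")

    def transcript(self, key: str) -> Transcript:
        """Look a transcript up by id or display name."""
        for t in self.transcripts:
            if t.transcript_id == key or t.variant_name == key:
                return t
        raise KeyError(key)


@dataclass
class DiscriminatingJunctionMap:
    """Per-variant sets of junctions found in that transcript and no other.

    Variants whose junctions are all shared with at least one other
    transcript have an empty set and are listed in ``unquantifiable`` —
    they are invisible to junction-based counting and the caller must know.
    """

    by_variant: dict[str, frozenset[Junction]]
    unquantifiable: list[str] = field(default_factory=list)

    def all_junctions(self) -> frozenset[Junction]:
        out: set[Junction] = set()
        for s in self.by_variant.values():
            out |= s
        return frozenset(out)

    def variant_of(self, junction: Junction) -> str | None:
        for name, s in self.by_variant.items():
            if junction in s:
                return name
        return None


def derive_junctions(transcript: Transcript) -> list[Junction]:
    """Junctions between adjacent genomic exon pairs of one transcript.

    Returns one junction per adjacent pair in genomic order; a single-exon
    transcript yields an empty list.  Raises ``ValueError`` on overlapping
    exons.
    """
    exons = sorted(transcript.exons, key=lambda e: e.start)
    junctions: list[Junction] = []
    for left, right in zip(exons, exons[1:]):
        if right.start <= left.end:
            raise ValueError(
                f"invalid transcript structure: overlapping exons in {transcript.transcript_id}"
            )
        junctions.append(Junction(left.chrom, left.end, right.start))
    return junctions


def discriminating_junctions(gene: GeneModel) -> DiscriminatingJunctionMap:
    """For each variant, the junctions present in no other transcript of the gene.

    The canonical transcript is treated the same way as every other variant:
    its set is the junctions unique to the canonical structure.  Uniqueness
    is judged within the supplied transcript set only.
    """
    per_tx = {t.variant_name: set(derive_junctions(t)) for t in gene.transcripts}
    by_variant: dict[str, frozenset[Junction]] = {}
    unquantifiable: list[str] = []
    for name, juncs in per_tx.items():
        others: set[Junction] = set()
        for other, oj in per_tx.items():
            if other != name:
                others |= oj
        unique = frozenset(juncs - others)
        by_variant[name] = unique
        if not unique:
            unquantifiable.append(name)
    return DiscriminatingJunctionMap(by_variant=by_variant, unquantifiable=unquantifiable)


def _contig_sequence(genome, chrom: str) -> str:
    """Fetch a full contig string from a dict-like or pyfaidx/SeqIO store."""
    try:
        seq = genome[chrom]
    except KeyError as exc:
        raise ValueError(f"sequence out of range: contig {chrom!r} absent") from exc
    return str(seq[:]) if not isinstance(seq, str) else seq


def spliced_sequence(transcript: Transcript, genome: Mapping[str, str]) -> str:
    """mRNA-ordered nucleotide sequence of a transcript.

    Exon sequences are concatenated in genomic order and, for minus-strand
    transcripts, reverse-complemented as a whole — equivalent to per-exon
    reverse complement in transcript-rank order.
    """
    chrom = transcript.chrom
    contig = _contig_sequence(genome, chrom)
    parts: list[str] = []
    for exon in sorted(transcript.exons, key=lambda e: e.start):
        if exon.start < 1 or exon.end > len(contig):
            raise ValueError(
                f"sequence out of range: exon {exon.start}-{exon.end} on {chrom} "
                f"(contig length {len(contig)})"
            )
        parts.append(contig[exon.start - 1 : exon.end])
    seq = "".join(parts).upper()
    if transcript.strand == "-":
        seq = reverse_complement(seq)
    return seq


# ---------------------------------------------------------------------------
# annotation parsing


def _open_db(annotation: str) -> gffutils.FeatureDB:
    return gffutils.create_db(
        annotation,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )


def _attr(feature, *names: str) -> str | None:
    for name in names:
        if name in feature.attributes:
            vals = feature.attributes[name]
            if vals:
                return vals[0]
    return None


def _exon_attribution(db: gffutils.FeatureDB, exon) -> tuple[str | None, str | None]:
    """(gene_id, transcript_id) of an exon, via GTF attributes or GFF3 Parent chain."""
    gene_id = _attr(exon, "gene_id", "geneID")
    tx_id = _attr(exon, "transcript_id", "transcriptID")
    if gene_id is not None and tx_id is not None:
        return gene_id, tx_id
    # GFF3: exon -> Parent transcript -> Parent gene
    for parent in db.parents(exon, level=1):
        tx_id = tx_id or parent.id
        g = _attr(parent, "gene_id") or next(
            (gp.id for gp in db.parents(parent, level=1)), None
        )
        gene_id = gene_id or g
        break
    return gene_id, tx_id


def parse_gene_models(
    annotation: str, gene_id: str, canonical_id: str
) -> GeneModel:
    """Parse one gene's transcript structures from a GTF or GFF3 file.

    ``annotation`` is a path (plain or gzip).  Exon features belonging to
    other genes are ignored.  Exons are sorted genomically within each
    transcript and ``transcript_rank`` assigned by strand.

    Raises ``ValueError`` with "gene not found" / "canonical transcript not
    found" / "malformed annotation" messages on the corresponding defects.
    """
    db = _open_db(annotation)

    exons_by_tx: dict[str, list] = {}
    meta_by_tx: dict[str, dict] = {}
    for exon in db.features_of_type("exon"):
        g, tx = _exon_attribution(db, exon)
        if g != gene_id or tx is None:
            continue
        if exon.end < exon.start:
            raise ValueError("malformed annotation: exon end < start")
        exons_by_tx.setdefault(tx, []).append(exon)
        meta = meta_by_tx.setdefault(tx, {})
        meta.setdefault("strand", exon.strand)
        meta.setdefault("chrom", exon.seqid)
        name = _attr(exon, "transcript_name", "Name")
        if name:
            meta.setdefault("variant_name", name)
        biotype = _attr(exon, "transcript_biotype", "transcript_type", "biotype")
        if biotype:
            meta.setdefault("biotype", biotype)

    if not exons_by_tx:
        raise ValueError(f"gene not found: {gene_id}")

    # transcript-level features may carry names/biotypes the exon lines lack
    for ftype in ("transcript", "mRNA"):
        for tx_feat in db.features_of_type(ftype):
            tid = _attr(tx_feat, "transcript_id") or tx_feat.id
            if tid not in exons_by_tx:
                continue
            meta = meta_by_tx[tid]
            name = _attr(tx_feat, "transcript_name", "Name")
            if name:
                meta["variant_name"] = meta.get("variant_name") or name
            biotype = _attr(tx_feat, "transcript_biotype", "transcript_type", "biotype")
            if biotype:
                meta["biotype"] = meta.get("biotype") or biotype

    cds_by_tx: dict[str, tuple[int, int]] = {}
    for cds in db.features_of_type("CDS"):
        g, tx = _exon_attribution(db, cds)
        if g != gene_id or tx not in exons_by_tx:
            continue
        lo, hi = cds_by_tx.get(tx, (cds.start, cds.end))
        cds_by_tx[tx] = (min(lo, cds.start), max(hi, cds.end))

    transcripts: list[Transcript] = []
    for tx_id, feats in exons_by_tx.items():
        meta = meta_by_tx[tx_id]
        strand = meta.get("strand") or "+"
        chrom = meta["chrom"]
        feats.sort(key=lambda f: f.start)
        n = len(feats)
        exons = [
            Exon(
                chrom=chrom,
                start=f.start,
                end=f.end,
                transcript_rank=(i + 1 if strand != "-" else n - i),
            )
            for i, f in enumerate(feats)
        ]
        cds = cds_by_tx.get(tx_id, (None, None))
        transcripts.append(
            Transcript(
                transcript_id=tx_id,
                variant_name=meta.get("variant_name", tx_id),
                biotype=meta.get("biotype", ""),
                strand=strand,
                exons=exons,
                cds_start=cds[0],
                cds_end=cds[1],
            )
        )

    transcripts.sort(key=lambda t: t.transcript_id)
    if not any(t.transcript_id == canonical_id for t in transcripts):
        raise ValueError(f"canonical transcript not found: {canonical_id}")

    first = transcripts[0]
    return GeneModel(
        gene_id=gene_id,
        chrom=first.chrom,
        strand=first.strand,
        canonical_id=canonical_id,
        transcripts=transcripts,
    )


def write_junction_catalogue(gene: GeneModel, path: str) -> None:
    """Write the per-transcript junction catalogue as TSV.

    Columns: variant_name, transcript_id, chrom, donor_end, acceptor_start,
    discriminating {true,false}.
    """
    dmap = discriminating_junctions(gene)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["variant_name", "transcript_id", "chrom", "donor_end", "acceptor_start", "discriminating"]
        )
        for t in gene.transcripts:
            unique = dmap.by_variant.get(t.variant_name, frozenset())
            for j in derive_junctions(t):
                w.writerow(
                    [
                        t.variant_name,
                        t.transcript_id,
                        j.chrom,
                        j.donor_end,
                        j.acceptor_start,
                        "true" if j in unique else "false",
                    ]
                )


def read_junction_catalogue(path: str) -> DiscriminatingJunctionMap:
    """Read a catalogue TSV back into a DiscriminatingJunctionMap.

    Only rows flagged discriminating=true enter the per-variant sets; the
    returned map is the counting catalogue.
    """
    by_variant: dict[str, set[Junction]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            by_variant.setdefault(row["variant_name"], set())
            if row["discriminating"].lower() == "true":
                by_variant[row["variant_name"]].add(
                    Junction(row["chrom"], int(row["donor_end"]), int(row["acceptor_start"]))
                )
    frozen = {k: frozenset(v) for k, v in by_variant.items()}
    return DiscriminatingJunctionMap(
        by_variant=frozen,
        unquantifiable=[k for k, v in frozen.items() if not v],
    )
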