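"""Junction-spanning qPCR primer validation and in-silico PCR.

To quantify a splice variant specifically, a qPCR primer must anneal across
the variant's discriminating splice junction, overlapping it by at least
8 bases on both the 5' and 3' sides — otherwise the primer co-amplifies
transcripts sharing one of the two exons.  This module checks that overlap
rule and predicts amplicon sizes by exact-match in-silico PCR on variant
transcript (cDNA) sequences: the forward primer is matched verbatim, the
reverse primer as its reverse complement, both hits must be unique, and the
amplicon runs from the start of the forward site to the end of the reverse
site, inclusive.  No mismatch tolerance and no melting-temperature model:
annealing is exact, case-insensitive, over the A/C/G/T alphabet only.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Mapping

from Bio.Seq import reverse_complement

__all__ = [
    "PrimerPair",
    "AmpliconReport",
    "validate_junction_primer",
    "in_silico_pcr",
    "read_primers_tsv",
    "write_amplicon_report",
]

MIN_JUNCTION_OVERLAP = 8  # nt on each side of the junction
_ALPHABET = set("ACGT")


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair targeting one splice variant.

    Both primers are written 5'->3'; the reverse primer anneals to the
    template as its reverse complement.  ``junction_offsets`` gives, for
    each primer that claims to span a junction, the 1-based position within
    the primer of the last base of the upstream exon.
    """

    name: str
    fwd: str
    rvs: str
    target_variant: str = ""
    junction_offsets: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        for label, seq in (("fwd", self.fwd), ("rvs", self.rvs)):
            up = seq.upper()
            bad = set(up) - _ALPHABET
            if bad:
                raise ValueError(
                    f"primer {self.name}/{label} contains non-ACGT symbols: {sorted(bad)}"
                )
            if len(up) < 15:
                raise ValueError(f"primer {self.name}/{label} shorter than 15 nt")


@dataclass(frozen=True)
class AmpliconReport:
    pair_name: str
    template_id: str
    amplicon_length: int
    fwd_start: int  # 1-based position of first fwd-site base on template
    fwd_end: int
    rvs_start: int
    rvs_end: int
    junction_rule_pass: Mapping[str, bool] | None = None


def validate_junction_primer(
    primer_length: int,
    junction_position_in_primer: int,
    min_overlap: int = MIN_JUNCTION_OVERLAP,
) -> bool:
    """Check the junction-overlap rule for one primer.

    ``junction_position_in_primer`` is the 1-based offset from the 5' end of
    the last base belonging to the upstream exon; the rule requires at
    least ``min_overlap`` bases on each side of the junction (inclusive).
    Raises ``ValueError`` when the junction falls outside the primer.
    """
    j = junction_position_in_primer
    if not 0 < j < primer_length:
        raise ValueError("primer does not span junction")
    return j >= min_overlap and (primer_length - j) >= min_overlap


def _find_all(template: str, query: str) -> list[int]:
    """0-based start positions of every exact occurrence of query."""
    hits = []
    start = 0
    while True:
        i = template.find(query, start)
        if i < 0:
            return hits
        hits.append(i)
        start = i + 1


def in_silico_pcr(
    pair: "PrimerPair | tuple[str, str]", template: str, template_id: str = "template"
) -> AmpliconReport:
    """Predict the amplicon of one primer pair on one template sequence.

    ``pair`` is a PrimerPair or a bare ``(fwd, rvs)`` tuple (useful for
    short probe-like oligos below the assay-primer length floor).  Exact,
    case-insensitive matching; each primer must hit the template exactly
    once ("ambiguous priming" otherwise, "primer does not anneal" when a
    site is missing or the sites are not in amplifiable orientation).  The
    amplicon spans the forward site's first base to the reverse site's
    last base, inclusive.
    """
    if not template:
        raise ValueError("template must be non-empty")
    if isinstance(pair, tuple):
        name, (fwd_seq, rvs_seq), offsets = "pair", pair, None
        bad = (set(fwd_seq.upper()) | set(rvs_seq.upper())) - _ALPHABET
        if bad:
            raise ValueError(f"primer contains non-ACGT symbols: {sorted(bad)}")
    else:
        name, fwd_seq, rvs_seq, offsets = pair.name, pair.fwd, pair.rvs, pair.junction_offsets
    t = template.upper()
    fwd = fwd_seq.upper()
    rvs_site = reverse_complement(rvs_seq.upper())

    fwd_hits = _find_all(t, fwd)
    rvs_hits = _find_all(t, rvs_site)
    if not fwd_hits or not rvs_hits:
        raise ValueError(f"primer does not anneal: {name} on {template_id}")
    if len(fwd_hits) > 1 or len(rvs_hits) > 1:
        raise ValueError(f"ambiguous priming: {name} on {template_id}")

    fwd_start0, rvs_start0 = fwd_hits[0], rvs_hits[0]
    fwd_end0 = fwd_start0 + len(fwd) - 1
    rvs_end0 = rvs_start0 + len(rvs_site) - 1
    if rvs_end0 < fwd_start0:
        raise ValueError(
            f"primer does not anneal: {name} sites in non-amplifiable orientation"
        )
    rule = None
    if offsets:
        lengths = {"fwd": len(fwd_seq), "rvs": len(rvs_seq)}
        rule = {
            label: validate_junction_primer(lengths[label], offset)
            for label, offset in offsets.items()
        }
    return AmpliconReport(
        pair_name=name,
        template_id=template_id,
        amplicon_length=rvs_end0 - fwd_start0 + 1,
        fwd_start=fwd_start0 + 1,
        fwd_end=fwd_end0 + 1,
        rvs_start=rvs_start0 + 1,
        rvs_end=rvs_end0 + 1,
        junction_rule_pass=rule,
    )


def p4hb_junction_primers() -> list[tuple[PrimerPair, int | None]]:
    """The published P4HB junction-spanning qPCR primer pairs.

    Returns (pair, reported amplicon length in bp or None) tuples, read
    from the packaged primer table.  The amplicon lengths are the assay's
    reported product sizes; predicting them from sequence requires the
    corresponding variant transcript sequences as templates.
    """
    from importlib.resources import files

    out: list[tuple[PrimerPair, int | None]] = []
    text = files("sjquant.data").joinpath("p4hb_primers.tsv").read_text()
    for row in csv.DictReader(text.splitlines(), delimiter="\t"):
        pair = PrimerPair(
            name=row["name"], fwd=row["fwd"], rvs=row["rvs"],
            target_variant=row["target_variant"],
        )
        bp = int(row["amplicon_bp"]) if row.get("amplicon_bp") else None
        out.append((pair, bp))
    return out


def read_primers_tsv(path: str) -> list[PrimerPair]:
    """Read primer pairs from TSV (name, fwd, rvs, target_variant)."""
    pairs = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            pairs.append(
                PrimerPair(
                    name=row["name"],
                    fwd=row["fwd"],
                    rvs=row["rvs"],
                    target_variant=row.get("target_variant", ""),
                )
            )
    return pairs


def write_amplicon_report(reports: Iterable[AmpliconReport], path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["pair_name", "template_id", "amplicon_length", "fwd_start",
             "fwd_end", "rvs_start", "rvs_end"]
        )
        for r in reports:
            w.writerow(
                [r.pair_name, r.template_id, r.amplicon_length, r.fwd_start,
                 r.fwd_end, r.rvs_start, r.rvs_end]
            )
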