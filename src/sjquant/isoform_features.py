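"""Project the canonical protein's domain map through splice-variant products.

Protein disulfide isomerase-family proteins are modular: catalytic
thioredoxin domains (a, a') carrying redox-active CGHC tetrapeptides,
substrate-binding domains (b, b'), an x-linker, and a C-terminal c domain
ending in the ER-retrieval signal KDEL.  A splice variant's product differs
from the canonical protein by whole exonic blocks, so a block alignment of
the two amino-acid sequences tells exactly which canonical residues the
variant retains.  Projecting a user-supplied domain map through that
alignment classifies each domain as intact, truncated or absent, and counts
surviving CGHC motifs — the basis for reasoning about which variants could
retain isomerase activity or ER residency.

Domain coordinates are input, never invented here: supply them as a
DomainMap or a TSV (domain, start_aa, end_aa).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from difflib import SequenceMatcher

__all__ = [
    "DomainMap",
    "DomainStatus",
    "DomainProjection",
    "read_domain_map",
    "protein_alignment_map",
    "project_domains",
    "motif_flags",
]

MIN_SHARED_BLOCK = 5  # aa; below this the sequences are not splice-related
CGHC = "CGHC"
KDEL = "KDEL"
STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class DomainMap:
    """Ordered, non-overlapping domain intervals on the canonical protein.

    ``domains``: tuples (name, start_aa, end_aa), 1-based inclusive,
    ascending.  ``cghc_positions``: 1-based start of each CGHC tetrapeptide
    (expected inside the catalytic domains).
    """

    domains: tuple[tuple[str, int, int], ...]
    cghc_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        prev_end = 0
        for name, start, end in self.domains:
            if start > end or start <= prev_end:
                raise ValueError(f"inconsistent domain map at {name} ({start}-{end})")
            prev_end = end

    @property
    def length_covered(self) -> int:
        return sum(end - start + 1 for _, start, end in self.domains)


@dataclass(frozen=True)
class DomainStatus:
    name: str
    status: str  # intact | truncated | absent
    retained_aa: int
    missing_aa: int


@dataclass(frozen=True)
class DomainProjection:
    """Per-domain retention tallies plus variant-level motif flags."""

    domains: tuple[DomainStatus, ...]
    cghc_count: int
    has_KDEL: bool | None = None
    has_start_codon: bool | None = None
    has_stop_codon: bool | None = None

    def domain(self, name: str) -> DomainStatus:
        for d in self.domains:
            if d.name == name:
                return d
        raise KeyError(name)


def read_domain_map(path: str) -> DomainMap:
    """Read a domain-map TSV (domain, start_aa, end_aa[, cghc column ignored])."""
    rows = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rows.append((row["domain"], int(row["start_aa"]), int(row["end_aa"])))
    return DomainMap(domains=tuple(rows))


def protein_alignment_map(canonical_protein: str, variant_protein: str) -> dict[int, int]:
    """Map variant residues onto canonical coordinates via exact-block alignment.

    Splice variants share exact exonic blocks with the canonical protein,
    so a longest-matching-block decomposition (ties broken leftmost) is the
    right alignment model — no substitution scoring.  Returns
    {variant_pos -> canonical_pos}, both 1-based; canonical positions
    absent from the values are the deletions.  Raises ``ValueError``
    ("unrelated sequences") when no shared block reaches 5 aa.
    """
    if not canonical_protein or not variant_protein:
        raise ValueError("both sequences must be non-empty")
    canon = canonical_protein.upper()
    var = variant_protein.upper()
    sm = SequenceMatcher(None, canon, var, autojunk=False)
    blocks = [b for b in sm.get_matching_blocks() if b.size > 0]
    if not blocks or max(b.size for b in blocks) < MIN_SHARED_BLOCK:
        raise ValueError("unrelated sequences: no shared block >= 5 aa")
    mapping: dict[int, int] = {}
    for b in blocks:
        for k in range(b.size):
            mapping[b.b + k + 1] = b.a + k + 1
    return mapping


def project_domains(
    alignment_map: dict[int, int],
    domains: DomainMap,
    canonical_length: int | None = None,
) -> DomainProjection:
    """Classify each canonical domain as intact/truncated/absent in a variant.

    ``alignment_map`` is the {variant_pos -> canonical_pos} map from
    :func:`protein_alignment_map` (an empty map means nothing retained).
    A CGHC motif counts as surviving only when all four of its canonical
    positions are retained.
    """
    retained = set(alignment_map.values())
    if canonical_length is not None:
        for _, start, end in domains.domains:
            if end > canonical_length:
                raise ValueError("inconsistent domain map: interval beyond canonical length")
    statuses: list[DomainStatus] = []
    for name, start, end in domains.domains:
        span = end - start + 1
        kept = sum(1 for p in range(start, end + 1) if p in retained)
        status = "intact" if kept == span else ("absent" if kept == 0 else "truncated")
        statuses.append(
            DomainStatus(name=name, status=status, retained_aa=kept, missing_aa=span - kept)
        )
    cghc = sum(
        1
        for pos in domains.cghc_positions
        if all(pos + k in retained for k in range(4))
    )
    return DomainProjection(domains=tuple(statuses), cghc_count=cghc)


def motif_flags(variant_protein: str, variant_cds: str | None = None) -> dict[str, bool | None]:
    """Terminal-KDEL, start-codon and stop-codon flags for one variant.

    ``has_KDEL`` is true only for an exact terminal KDEL tetrapeptide.
    Codon flags need the annotated CDS nucleotide sequence; without it they
    are None (unknown), matching variants annotated without a classical
    start or stop.
    """
    protein = variant_protein.upper().rstrip("*")
    flags: dict[str, bool | None] = {
        "has_KDEL": protein.endswith(KDEL),
        "has_start_codon": None,
        "has_stop_codon": None,
    }
    if variant_cds is not None:
        cds = variant_cds.upper().replace("U", "T")
        flags["has_start_codon"] = cds.startswith("ATG")
        flags["has_stop_codon"] = len(cds) >= 3 and cds[-3:] in STOPS
    return flags


def write_architecture_report(
    rows: dict[str, DomainProjection], domains: DomainMap, path: str
) -> None:
    """TSV report: variant, per-domain status/retained/missing, motif flags."""
    names = [name for name, _, _ in domains.domains]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        header = ["variant"]
        for n in names:
            header += [f"{n}_status", f"{n}_retained_aa", f"{n}_missing_aa"]
        header += ["cghc_count", "has_KDEL", "has_start_codon", "has_stop_codon"]
        w.writerow(header)
        for variant, proj in rows.items():
            row: list = [variant]
            for n in names:
                d = proj.domain(n)
                row += [d.status, d.retained_aa, d.missing_aa]
            row += [proj.cghc_count, proj.has_KDEL, proj.has_start_codon, proj.has_stop_codon]
            w.writerow(row)
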