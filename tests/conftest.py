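"""Shared fixtures: hand-built alignment records and toy annotations."""

from __future__ import annotations

import re

import pysam
import pytest

from sjquant.gene_models import Exon, GeneModel, Transcript

HEADER = pysam.AlignmentHeader.from_dict(
    {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 1_000_000}]}
)


def _read_len(cigar: str) -> int:
    return sum(int(n) for n, _ in re.findall(r"(\d+)([MIS=X])", cigar))


def make_record(
    pos: int,
    cigar: str,
    flag: int = 0,
    mapq: int = 60,
    qname: str = "read",
    chrom: str = "chr1",
    header: pysam.AlignmentHeader = HEADER,
) -> pysam.AlignedSegment:
    """Build one alignment record; ``pos`` is the 1-based SAM POS."""
    rec = pysam.AlignedSegment(header)
    rec.query_name = qname
    rec.flag = flag
    rec.reference_id = list(header.references).index(chrom)
    rec.reference_start = pos - 1
    rec.mapping_quality = mapq
    rec.cigarstring = cigar
    n = _read_len(cigar)
    rec.query_sequence = "A" * n
    rec.query_qualities = pysam.qualitystring_to_array("I" * n)
    return rec


@pytest.fixture
def record_factory():
    return make_record


def two_transcript_gene() -> GeneModel:
    """Plus-strand 4-exon canonical plus an exon-3-skipping variant."""
    exon_bounds = [(101, 200), (301, 400), (501, 600), (701, 800)]

    def exons(keep):
        return [
            Exon("chr1", s, e, rank)
            for rank, (s, e) in enumerate((exon_bounds[i - 1] for i in keep), start=1)
        ]

    canonical = Transcript("tx1", "CANONICAL", "protein_coding", "+", exons([1, 2, 3, 4]))
    skip3 = Transcript("tx2", "SKIP3", "protein_coding", "+", exons([1, 2, 4]))
    return GeneModel("g1", "chr1", "+", "tx1", [canonical, skip3])


@pytest.fixture
def skip_gene() -> GeneModel:
    return two_transcript_gene()


TOY_GTF = """\
chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1"; transcript_name "G1-001";
chr1\tsrc\texon\t301\t400\t.\t+\t.\tgene_id "g1"; transcript_id "t1"; transcript_name "G1-001";
"""


@pytest.fixture
def toy_gtf(tmp_path):
    path = tmp_path / "toy.gtf"
    path.write_text(TOY_GTF)
    return str(path)
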