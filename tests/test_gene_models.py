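"""Annotation parsing, junction derivation, and discriminating-set logic."""

import numpy as np
import pytest

from sjquant.gene_models import (
    Exon,
    GeneModel,
    Junction,
    Transcript,
    derive_junctions,
    discriminating_junctions,
    parse_gene_models,
    read_junction_catalogue,
    spliced_sequence,
    write_junction_catalogue,
)

# ----------------------------------------------------------------------
# parsing


GTF_TWO_GENES = """\
chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
chr1\tsrc\texon\t301\t400\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
chr1\tsrc\texon\t5000\t5100\t.\t-\t.\tgene_id "g2"; transcript_id "t9";
chr1\tsrc\texon\t5300\t5400\t.\t-\t.\tgene_id "g2"; transcript_id "t9";
chr1\tsrc\texon\t5300\t5400\t.\t-\t.\tgene_id "g2"; transcript_id "t10";
"""

GFF3_TOY = """\
##gff-version 3
chr1\tsrc\tgene\t101\t400\t.\t+\t.\tID=g1
chr1\tsrc\tmRNA\t101\t400\t.\t+\t.\tID=t1;Parent=g1;Name=G1-001
chr1\tsrc\texon\t101\t200\t.\t+\t.\tID=e1;Parent=t1
chr1\tsrc\texon\t301\t400\t.\t+\t.\tID=e2;Parent=t1
chr1\tsrc\tCDS\t150\t350\t.\t+\t0\tID=c1;Parent=t1
"""


def test_parse_single_transcript_plus_strand(toy_gtf):
    gene = parse_gene_models(toy_gtf, "g1", "t1")
    (tx,) = gene.transcripts
    assert tx.variant_name == "G1-001"
    assert [(e.start, e.end, e.transcript_rank) for e in tx.exons] == [
        (101, 200, 1),
        (301, 400, 2),
    ]


def test_parse_minus_strand_rank_is_rightmost_first(tmp_path):
    gtf = tmp_path / "minus.gtf"
    gtf.write_text(
        'chr1\tsrc\texon\t101\t200\t.\t-\t.\tgene_id "g1"; transcript_id "t1";\n'
        'chr1\tsrc\texon\t301\t400\t.\t-\t.\tgene_id "g1"; transcript_id "t1";\n'
    )
    gene = parse_gene_models(str(gtf), "g1", "t1")
    ranks = {(e.start, e.end): e.transcript_rank for e in gene.transcripts[0].exons}
    assert ranks[(301, 400)] == 1 and ranks[(101, 200)] == 2


def test_parse_selects_requested_gene_only(tmp_path):
    gtf = tmp_path / "two.gtf"
    gtf.write_text(GTF_TWO_GENES)
    gene = parse_gene_models(str(gtf), "g2", "t9")
    # brute-force text-scan oracle: transcripts of g2 named in the file
    expected_tx = {
        line.split('transcript_id "')[1].split('"')[0]
        for line in GTF_TWO_GENES.splitlines()
        if 'gene_id "g2"' in line
    }
    assert {t.transcript_id for t in gene.transcripts} == expected_tx
    expected_exons = sum(1 for line in GTF_TWO_GENES.splitlines() if 'gene_id "g2"' in line)
    assert sum(len(t.exons) for t in gene.transcripts) == expected_exons


def test_parse_gff3_with_parent_chain(tmp_path):
    gff = tmp_path / "toy.gff3"
    gff.write_text(GFF3_TOY)
    gene = parse_gene_models(str(gff), "g1", "t1")
    (tx,) = gene.transcripts
    assert tx.variant_name == "G1-001"
    assert len(tx.exons) == 2
    assert (tx.cds_start, tx.cds_end) == (150, 350)


@pytest.mark.parametrize(
    "gene_id,canonical,msg",
    [("nope", "t1", "gene not found"), ("g1", "nope", "canonical transcript not found")],
)
def test_parse_errors(toy_gtf, gene_id, canonical, msg):
    with pytest.raises(ValueError, match=msg):
        parse_gene_models(toy_gtf, gene_id, canonical)


def test_malformed_exon_rejected():
    with pytest.raises(ValueError, match="malformed annotation"):
        Exon("chr1", 200, 100, 1)


# ----------------------------------------------------------------------
# junction derivation


def _tx(bounds, strand="+"):
    exons = [Exon("chr1", s, e, i + 1) for i, (s, e) in enumerate(bounds)]
    return Transcript("t", "T", "pc", strand, exons)


def test_two_exon_junction():
    assert derive_junctions(_tx([(101, 200), (301, 400)])) == [Junction("chr1", 200, 301)]


def test_single_exon_no_junction():
    assert derive_junctions(_tx([(101, 800)])) == []


def test_exon_skip_junction_joins_flanking_exons(skip_gene):
    # manual enumeration over the skipping transcript's adjacent pairs:
    # (101-200, 301-400) and (301-400, 701-800)
    skip = skip_gene.transcript("SKIP3")
    assert derive_junctions(skip) == [
        Junction("chr1", 200, 301),
        Junction("chr1", 400, 701),
    ]


def test_overlapping_exons_rejected():
    with pytest.raises(ValueError, match="invalid transcript structure"):
        derive_junctions(_tx([(101, 300), (250, 400)]))


def test_junction_requires_intron():
    with pytest.raises(ValueError, match="invalid junction"):
        Junction("chr1", 200, 201)


# ----------------------------------------------------------------------
# discriminating junctions


def test_skip_variant_discriminated_by_skip_junction(skip_gene):
    dmap = discriminating_junctions(skip_gene)
    # brute-force set difference computed by hand over the two junction lists
    assert dmap.by_variant["SKIP3"] == {Junction("chr1", 400, 701)}
    assert dmap.by_variant["CANONICAL"] == {
        Junction("chr1", 400, 501),
        Junction("chr1", 600, 701),
    }
    assert dmap.unquantifiable == []


def test_identical_transcripts_are_unquantifiable():
    t1 = _tx([(101, 200), (301, 400)])
    t2 = Transcript("t2", "T2", "pc", "+", t1.exons)
    gene = GeneModel("g", "chr1", "+", "t", [t1, t2])
    dmap = discriminating_junctions(gene)
    assert dmap.by_variant["T"] == frozenset() and dmap.by_variant["T2"] == frozenset()
    assert set(dmap.unquantifiable) == {"T", "T2"}


def _many_variant_gene(n_exons=11, n_variants=9, seed=5):
    """Canonical + single-exon-skip variants, one per internal exon."""
    rng = np.random.default_rng(seed)
    bounds = []
    pos = 1001
    for _ in range(n_exons):
        length = int(rng.integers(80, 300))
        bounds.append((pos, pos + length - 1))
        pos += length + int(rng.integers(100, 900))
    txs = [
        Transcript(
            "tx0", "CANON", "pc", "+",
            [Exon("chr1", s, e, i + 1) for i, (s, e) in enumerate(bounds)],
        )
    ]
    for v in range(n_variants):
        skip = v + 2  # skip one internal exon per variant
        keep = [b for i, b in enumerate(bounds, start=1) if i != skip]
        txs.append(
            Transcript(
                f"tx{v+1}", f"VAR{v+1}", "pc", "+",
                [Exon("chr1", s, e, i + 1) for i, (s, e) in enumerate(keep)],
            )
        )
    return GeneModel("g", "chr1", "+", "tx0", txs)


def test_ten_variant_gene_sets_pairwise_disjoint():
    gene = _many_variant_gene()
    dmap = discriminating_junctions(gene)
    assert len(dmap.by_variant) == 10
    names = list(dmap.by_variant)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            assert not (dmap.by_variant[a] & dmap.by_variant[b])
    # each member junction occurs in exactly one transcript of the gene
    for name, juncs in dmap.by_variant.items():
        for j in juncs:
            carriers = [
                t.variant_name
                for t in gene.transcripts
                if j in set(derive_junctions(t))
            ]
            assert carriers == [name]


def test_junction_count_matches_exon_count_randomized():
    rng = np.random.default_rng(11)
    for _ in range(20):
        n = int(rng.integers(1, 12))
        pos = 101
        bounds = []
        for _ in range(n):
            ln = int(rng.integers(30, 400))
            bounds.append((pos, pos + ln - 1))
            pos += ln + int(rng.integers(50, 500))
        tx = _tx(bounds)
        assert len(derive_junctions(tx)) == n - 1


# ----------------------------------------------------------------------
# spliced sequence


GENOME = {"chr1": "ACGTTTGCA"}


def test_spliced_sequence_plus_strand():
    tx = _tx([(1, 3), (7, 9)])
    assert spliced_sequence(tx, GENOME) == "ACGGCA"


def test_spliced_sequence_minus_strand():
    tx = _tx([(1, 3), (7, 9)], strand="-")
    assert spliced_sequence(tx, GENOME) == "TGCCGT"


def test_spliced_sequence_single_exon_identity():
    tx = _tx([(1, 9)])
    assert spliced_sequence(tx, GENOME) == GENOME["chr1"]


def test_spliced_sequence_out_of_range():
    with pytest.raises(ValueError, match="sequence out of range"):
        spliced_sequence(_tx([(5, 20)]), GENOME)


def test_spliced_sequence_length_and_strand_mirror():
    rng = np.random.default_rng(3)
    contig = "".join(rng.choice(list("ACGT"), size=500))
    genome = {"chr1": contig}
    bounds = [(11, 60), (101, 180), (301, 330)]
    plus = _tx(bounds, "+")
    minus = _tx(bounds, "-")
    fwd = spliced_sequence(plus, genome)
    rev = spliced_sequence(minus, genome)
    assert len(fwd) == sum(e - s + 1 for s, e in bounds)
    from Bio.Seq import reverse_complement

    assert rev == reverse_complement(fwd)


# ----------------------------------------------------------------------
# catalogue round trip


def test_catalogue_tsv_round_trip(skip_gene, tmp_path):
    path = tmp_path / "catalogue.tsv"
    write_junction_catalogue(skip_gene, str(path))
    dmap = read_junction_catalogue(str(path))
    assert dmap.by_variant == discriminating_junctions(skip_gene).by_variant
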