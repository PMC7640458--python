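"""SJ TPM arithmetic, fractions, replicate averaging, group summaries."""

import math

import numpy as np
import pandas as pd
import pytest

from sjquant.quantify import (
    aggregate_groups,
    average_replicates,
    build_matrix,
    fraction_of_expression,
    presence_summary,
    sj_tpm,
    variant_fraction,
)


# ----------------------------------------------------------------------
# formula


@pytest.mark.parametrize(
    "spliced,total,expected",
    [
        (5, 1_000_000, 5.0),
        (0, 123, 0.0),
        # hand arithmetic at a 2x10^8-read library depth
        (7, 200_000_000, 0.035),
    ],
)
def test_sj_tpm_examples(spliced, total, expected):
    assert sj_tpm(spliced, total) == pytest.approx(expected)


def test_sj_tpm_empty_library_rejected():
    with pytest.raises(ValueError, match="empty library"):
        sj_tpm(5, 0)


def test_sj_tpm_scale_invariance():
    rng = np.random.default_rng(0)
    for _ in range(25):
        spliced = int(rng.integers(0, 1000))
        total = int(rng.integers(1000, 10_000_000))
        k = int(rng.integers(2, 50))
        assert sj_tpm(spliced * k, total * k) == pytest.approx(sj_tpm(spliced, total))


def test_variant_fraction_examples():
    assert variant_fraction(3, 1000) == (pytest.approx(0.003), pytest.approx(0.3))
    assert variant_fraction(0, 1000) == (0.0, 0.0)
    with pytest.raises(ValueError, match="gene not expressed"):
        variant_fraction(3, 0)


def test_variant_fraction_binomial_recovery():
    """A sample built to 0.7% of gene reads recovers p within 3 binomial SE."""
    rng = np.random.default_rng(2024)
    p, n_gene = 0.007, 50_000
    spliced = int(rng.binomial(n_gene, p))
    prop, _ = variant_fraction(spliced, n_gene)
    se = math.sqrt(p * (1 - p) / n_gene)
    assert abs(prop - p) <= 3 * se


# ----------------------------------------------------------------------
# matrix assembly


def _counts_long(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "variant_name", "spliced_reads", "total_reads", "gene_reads"]
    )


def test_build_matrix_sums_junctions_per_variant():
    # a variant with two discriminating junctions: counts summed before normalizing
    df = _counts_long(
        [
            ("s1", "V1", 3, 1_000_000, 1000),
            ("s1", "V1", 2, 1_000_000, 1000),
            ("s1", "V2", 4, 1_000_000, 1000),
        ]
    )
    m = build_matrix(df)
    assert m.counts.loc["s1", "V1"] == 5
    assert m.sjtpm.loc["s1", "V1"] == pytest.approx(5.0)
    assert m.fractions.loc["s1", "V2"] == pytest.approx(0.004)


def test_build_matrix_rejects_empty_library():
    df = _counts_long([("s1", "V1", 0, 0, 0)])
    with pytest.raises(ValueError, match="empty library"):
        build_matrix(df)


def _matrix_70_samples():
    """70 samples, 2 variants; 6 donors contribute triplicates."""
    rng = np.random.default_rng(7)
    rows = []
    sample_ids = [f"s{i:02d}" for i in range(70)]
    for s in sample_ids:
        total = int(rng.integers(500_000, 2_000_000))
        gene = int(total * 0.01)
        rows += [
            (s, "V1", int(rng.integers(0, 50)), total, gene),
            (s, "V2", int(rng.integers(0, 5)), total, gene),
        ]
    sheet = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": ["blood" if i % 2 else "muscle" for i in range(70)],
        }
    )
    rep_map = {}
    for d in range(6):  # donors d0..d5, three replicates each
        for k in range(3):
            rep_map[sample_ids[d * 3 + k]] = f"donor{d}"
    return build_matrix(_counts_long(rows), sheet), rep_map


def test_average_replicates_triplicate_mean():
    df = _counts_long(
        [(s, "V1", c, 1_000_000, 1000) for s, c in [("a", 3), ("b", 6), ("c", 9)]]
    )
    m = build_matrix(df)
    out = average_replicates(m, {"a": "d", "b": "d", "c": "d"})
    assert list(out.sjtpm.index) == ["d"]
    assert out.sjtpm.loc["d", "V1"] == pytest.approx(6.0)


def test_average_replicates_singleton_identity():
    df = _counts_long([("a", "V1", 3, 1_000_000, 1000)])
    m = build_matrix(df)
    out = average_replicates(m, {})
    pd.testing.assert_frame_equal(out.sjtpm, m.sjtpm)


def test_average_replicates_row_count_70_samples():
    m, rep_map = _matrix_70_samples()
    out = average_replicates(m, rep_map)
    # counting oracle: samples minus sum of (group_size - 1) over groups
    group_sizes = pd.Series(rep_map).value_counts()
    expected = 70 - int((group_sizes - 1).sum())
    assert len(out.sjtpm) == expected == 58


def test_average_replicates_unknown_member():
    df = _counts_long([("a", "V1", 3, 1_000_000, 1000)])
    m = build_matrix(df)
    with pytest.raises(ValueError, match="unknown replicate member"):
        average_replicates(m, {"ghost": "d"})


# ----------------------------------------------------------------------
# group aggregation


def _group_matrix(values, groups):
    rows = [(f"s{i}", "V1", v, 1_000_000, 1000) for i, v in enumerate(values)]
    sheet = pd.DataFrame(
        {"sample_id": [f"s{i}" for i in range(len(values))], "group": groups}
    )
    return build_matrix(_counts_long(rows), sheet)


def test_aggregate_groups_mean_and_sample_sd():
    m = _group_matrix([2, 4], ["g", "g"])
    out = aggregate_groups(m, "group").set_index(["group", "variant"])
    assert out.loc[("g", "V1"), "mean"] == pytest.approx(3.0)
    assert out.loc[("g", "V1"), "sd"] == pytest.approx(math.sqrt(2))
    assert out.loc[("g", "V1"), "n"] == 2


def test_aggregate_groups_singleton_sd_zero():
    m = _group_matrix([5], ["g"])
    out = aggregate_groups(m, "group")
    assert out.loc[0, "mean"] == pytest.approx(5.0) and out.loc[0, "sd"] == 0.0


def test_aggregate_groups_all_zero():
    m = _group_matrix([0, 0, 0], ["g"] * 3)
    out = aggregate_groups(m, "group")
    assert out.loc[0, "mean"] == 0.0 and out.loc[0, "sd"] == 0.0


def test_aggregate_groups_missing_column():
    m = _group_matrix([1, 2], ["g", "g"])
    with pytest.raises(ValueError, match="missing metadata column"):
        aggregate_groups(m, "tissue")


def test_average_then_aggregate_equals_direct_when_balanced():
    """With balanced replicate groups, replicate-then-group averaging of SJ TPM
    equals averaging donor means computed directly."""
    rng = np.random.default_rng(12)
    rows, sheet_rows, rep_map = [], [], {}
    for d in range(4):
        for k in range(3):
            s = f"s{d}_{k}"
            rows.append((s, "V1", int(rng.integers(0, 100)), 1_000_000, 1000))
            sheet_rows.append({"sample_id": s, "group": "g1" if d < 2 else "g2"})
            rep_map[s] = f"d{d}"
    m = build_matrix(_counts_long(rows), pd.DataFrame(sheet_rows))
    collapsed = average_replicates(m, rep_map)
    out = aggregate_groups(collapsed, "group").set_index("group")
    direct = m.sjtpm.groupby(m.meta["group"]).mean()  # balanced => equal
    for g in ["g1", "g2"]:
        assert out.loc[g, "mean"] == pytest.approx(direct.loc[g, "V1"])


# ----------------------------------------------------------------------
# presence & fraction of expression


def test_presence_summary_constructed_28_of_70():
    rng = np.random.default_rng(3)
    rows = []
    detected = set(rng.choice(70, size=28, replace=False))
    for i in range(70):
        rows.append((f"s{i:02d}", "V1", 1 if i in detected else 0, 1_000_000, 1000))
    m = build_matrix(_counts_long(rows))
    assert presence_summary(m).loc["V1"] == 28


def test_presence_monotone_in_threshold():
    m, _ = _matrix_70_samples()
    prev = None
    for thr in [1, 2, 5, 10, 1000]:
        cur = presence_summary(m, thr)
        if prev is not None:
            assert (cur <= prev).all()
        prev = cur
    assert (presence_summary(m, 10**9) == 0).all()


def test_fraction_of_expression_both_views_sum_to_one():
    m, _ = _matrix_70_samples()
    for how in ["pooled", "per_sample"]:
        shares = fraction_of_expression(m, how=how)
        assert shares.sum() == pytest.approx(1.0)
        assert (shares >= 0).all()
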