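"""Expression statistics over junction counts: SJ TPM, fractions, summaries.

SJ TPM (Splice Junction Tags Per Million) is the per-variant expression
unit: reads spanning a variant's discriminating junction(s), divided by the
total number of reads in the library, times 10^6.  The gene-relative
*fraction* instead divides by the number of filtered reads overlapping the
gene span, giving the share of the gene's output attributable to the
variant.

A variant with several discriminating junctions is quantified by summing
its junction counts before normalizing (one number per variant); the
per-junction breakdown stays available in the counts table.  Fractions of
different variants are comparable with each other but are not forced to sum
to 1: discriminating-junction counts are not a partition of gene reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SJTPMMatrix",
    "sj_tpm",
    "variant_fraction",
    "build_matrix",
    "average_replicates",
    "aggregate_groups",
    "presence_summary",
    "fraction_of_expression",
]

SCALE = 1_000_000


def sj_tpm(spliced_reads: float, total_reads: float) -> float:
    """spliced_reads / total_reads × 10^6.

    Raises ``ValueError`` ("empty library") for total_reads == 0 rather
    than silently returning 0/0.
    """
    if total_reads <= 0:
        raise ValueError("empty library: total_reads must be > 0")
    if spliced_reads < 0:
        raise ValueError("spliced_reads must be >= 0")
    return spliced_reads / total_reads * SCALE


def variant_fraction(variant_spliced_reads: float, gene_reads: float) -> tuple[float, float]:
    """Gene-relative share of a variant: (proportion, percent).

    Raises ``ValueError`` ("gene not expressed in sample") when gene_reads
    is 0.
    """
    if gene_reads <= 0:
        raise ValueError("gene not expressed in sample: gene_reads must be > 0")
    if variant_spliced_reads < 0:
        raise ValueError("variant_spliced_reads must be >= 0")
    p = variant_spliced_reads / gene_reads
    return p, p * 100.0


@dataclass
class SJTPMMatrix:
    """Samples × variants expression statistics.

    ``sjtpm``, ``counts`` and ``fractions`` are aligned DataFrames indexed
    by sample_id with one column per variant_name; ``meta`` carries sample
    metadata (group, replicate_of, ...) on the same index, and
    ``total_reads`` / ``gene_reads`` the per-sample denominators.
    """

    sjtpm: pd.DataFrame
    counts: pd.DataFrame
    fractions: pd.DataFrame
    total_reads: pd.Series
    gene_reads: pd.Series
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def samples(self) -> list[str]:
        return list(self.sjtpm.index)

    @property
    def variants(self) -> list[str]:
        return list(self.sjtpm.columns)


def build_matrix(
    counts_long: pd.DataFrame, sample_sheet: pd.DataFrame | None = None
) -> SJTPMMatrix:
    """Assemble the SJ TPM matrix from the long-format counts table.

    ``counts_long`` has the counts-TSV columns (sample_id, variant_name,
    spliced_reads, total_reads, gene_reads); junction counts of one variant
    are summed per sample.  ``sample_sheet`` (sample_id, group,
    replicate_of, ...) attaches metadata.  Samples with total_reads == 0
    raise "empty library"; fractions are NaN where gene_reads == 0.
    """
    required = {"sample_id", "variant_name", "spliced_reads", "total_reads", "gene_reads"}
    missing = required - set(counts_long.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")

    per_variant = (
        counts_long.groupby(["sample_id", "variant_name"], sort=True)["spliced_reads"]
        .sum()
        .unstack(fill_value=0)
    )
    denoms = counts_long.groupby("sample_id")[["total_reads", "gene_reads"]].first()
    total = denoms["total_reads"].astype(float)
    gene = denoms["gene_reads"].astype(float)
    if (total <= 0).any():
        bad = list(total.index[total <= 0])
        raise ValueError(f"empty library: total_reads == 0 for samples {bad}")

    tpm = per_variant.div(total, axis=0) * SCALE
    frac = per_variant.div(gene.where(gene > 0), axis=0)

    meta = pd.DataFrame(index=per_variant.index)
    if sample_sheet is not None:
        meta = sample_sheet.set_index("sample_id").reindex(per_variant.index)
    return SJTPMMatrix(
        sjtpm=tpm,
        counts=per_variant,
        fractions=frac,
        total_reads=denoms["total_reads"],
        gene_reads=denoms["gene_reads"],
        meta=meta,
    )


def average_replicates(matrix: SJTPMMatrix, replicate_map: Mapping[str, str]) -> SJTPMMatrix:
    """Collapse technical/biological replicates to one row per donor.

    ``replicate_map`` maps sample_id → donor id; samples not listed map to
    themselves.  SJ TPM and fractions are averaged arithmetically; raw
    counts and denominators are summed (so the collapsed row remains a
    valid count table).  Metadata propagates where identical across the
    replicates of a donor, else becomes NA.
    """
    unknown = set(replicate_map) - set(matrix.samples)
    if unknown:
        raise ValueError(f"unknown replicate member: {sorted(unknown)}")
    donor = pd.Series(
        {s: replicate_map.get(s, s) for s in matrix.samples}, name="donor"
    )

    def _mean(df: pd.DataFrame) -> pd.DataFrame:
        return df.groupby(donor).mean().rename_axis("sample_id")

    def _sum(obj):
        return obj.groupby(donor).sum().rename_axis("sample_id")

    meta = pd.DataFrame(index=_mean(matrix.sjtpm).index)
    if not matrix.meta.empty:
        collapsed = {}
        for col in matrix.meta.columns:
            per_donor = matrix.meta[col].groupby(donor).agg(
                lambda v: v.iloc[0] if v.nunique(dropna=False) == 1 else pd.NA
            )
            collapsed[col] = per_donor
        meta = pd.DataFrame(collapsed)
    return SJTPMMatrix(
        sjtpm=_mean(matrix.sjtpm),
        counts=_sum(matrix.counts),
        fractions=_mean(matrix.fractions),
        total_reads=_sum(matrix.total_reads),
        gene_reads=_sum(matrix.gene_reads),
        meta=meta,
    )


def aggregate_groups(matrix: SJTPMMatrix, group_key: str) -> pd.DataFrame:
    """Per-group mean and sample SD (ddof=1; 0 for singletons) of SJ TPM.

    Returns a tidy frame: group, variant, mean, sd, n.
    """
    if group_key not in matrix.meta.columns:
        raise ValueError(f"missing metadata column: {group_key}")
    groups = matrix.meta[group_key]
    rows = []
    for g, idx in matrix.sjtpm.groupby(groups).groups.items():
        sub = matrix.sjtpm.loc[idx]
        mean = sub.mean()
        sd = sub.std(ddof=1).fillna(0.0) if len(sub) > 1 else pd.Series(0.0, index=sub.columns)
        for variant in sub.columns:
            rows.append(
                {"group": g, "variant": variant, "mean": mean[variant],
                 "sd": sd[variant], "n": len(sub)}
            )
    return pd.DataFrame(rows, columns=["group", "variant", "mean", "sd", "n"])


def presence_summary(matrix: SJTPMMatrix, detection_threshold: int = 1) -> pd.Series:
    """Number of samples with raw junction count >= threshold, per variant."""
    return (matrix.counts >= detection_threshold).sum(axis=0).astype(int)


def fraction_of_expression(matrix: SJTPMMatrix, how: str = "pooled") -> pd.Series:
    """Share of total isoform SJ TPM attributable to each variant.

    ``how="pooled"`` sums SJ TPM over all samples first; ``how="per_sample"``
    computes per-sample shares and averages them (samples with zero total
    isoform signal are skipped).  Both views are offered because summing
    first weights deep/high-signal samples more.
    """
    if how == "pooled":
        total = matrix.sjtpm.sum(axis=0)
        s = total.sum()
        if s == 0:
            return total * 0.0
        return total / s
    if how == "per_sample":
        row_tot = matrix.sjtpm.sum(axis=1)
        nz = row_tot > 0
        if not nz.any():
            return matrix.sjtpm.sum(axis=0) * 0.0
        shares = matrix.sjtpm.loc[nz].div(row_tot[nz], axis=0)
        return shares.mean(axis=0)
    raise ValueError("how must be 'pooled' or 'per_sample'")
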