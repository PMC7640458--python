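"""End-to-end orchestration: annotation -> counting -> quantification.

Drives the whole pipeline over a sample sheet and writes the report
bundle: junction catalogue, per-sample counts, SJ TPM / fraction matrices,
group summaries and a presence table, each TSV stamped with the package
version and a hash of the run configuration so a rerun is verifiable.
Per-sample failures abort the run by default (``keep_going`` skips the
failing sample instead, with the gap recorded in the log — silent sample
drop would bias group summaries).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .gene_models import (
    GeneModel,
    discriminating_junctions,
    parse_gene_models,
    write_junction_catalogue,
)
from .junction_counter import FilterConfig, count_junctions, write_counts_tsv
from .quantify import (
    SJTPMMatrix,
    aggregate_groups,
    build_matrix,
    presence_summary,
)
from . import quantify

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    annotation: str
    gene_id: str
    canonical_id: str
    sample_sheet: str
    out_dir: str
    filters: FilterConfig = field(default_factory=FilterConfig)
    detection_threshold: int = 1
    group_key: str = "group"
    keep_going: bool = False
    log_level: str = "INFO"

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _stamped_tsv(df: pd.DataFrame, path: str, cfg: RunConfig, index: bool) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sjquant {__version__} config_hash={cfg.config_hash()}\n")
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def _read_sample_sheet(path: str) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "sample_id" not in sheet.columns or "path" not in sheet.columns:
        raise ValueError("sample sheet needs sample_id and path columns")
    if sheet.empty:
        raise ValueError("no samples")
    return sheet


def run_pipeline(cfg: RunConfig) -> dict[str, str]:
    """Run catalogue -> count -> quantify; returns {table name: file path}.

    Outputs under ``cfg.out_dir``: junctions.tsv, counts.tsv,
    sjtpm_matrix.tsv, fractions.tsv, group_summary.tsv, presence.tsv, plus
    run_config.json (the config echoed verbatim) and run.log.
    """
    os.makedirs(cfg.out_dir, exist_ok=True)
    handler = logging.FileHandler(os.path.join(cfg.out_dir, "run.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("sjquant")
    root.addHandler(handler)
    root.setLevel(cfg.log_level)
    try:
        log.info("sjquant %s config_hash=%s", __version__, cfg.config_hash())
        log.info("filters: %s", cfg.filters)
        with open(os.path.join(cfg.out_dir, "run_config.json"), "w") as fh:
            json.dump(dataclasses.asdict(cfg), fh, indent=2, sort_keys=True)

        sheet = _read_sample_sheet(cfg.sample_sheet)
        gene = parse_gene_models(cfg.annotation, cfg.gene_id, cfg.canonical_id)
        catalogue = discriminating_junctions(gene)
        paths = {"junctions": os.path.join(cfg.out_dir, "junctions.tsv")}
        write_junction_catalogue(gene, paths["junctions"])

        tables = []
        for _, row in sheet.iterrows():
            try:
                tables.append(
                    count_junctions(
                        row["path"], catalogue, gene, cfg.filters, sample_id=row["sample_id"]
                    )
                )
            except Exception as exc:
                msg = f"sample {row['sample_id']}: {exc}"
                if cfg.keep_going:
                    log.error("skipping incomplete sample — %s", msg)
                    continue
                raise RuntimeError(msg) from exc
        if not tables:
            raise RuntimeError("no samples produced counts")

        paths["counts"] = os.path.join(cfg.out_dir, "counts.tsv")
        write_counts_tsv(tables, catalogue, paths["counts"])

        counts_long = pd.read_csv(paths["counts"], sep="\t")
        matrix = build_matrix(counts_long, sheet.drop(columns=["path"]))

        if "replicate_of" in sheet.columns:
            rep = {
                s: d
                for s, d in zip(sheet["sample_id"], sheet["replicate_of"])
                if isinstance(d, str) and d
            }
            if rep:
                matrix = quantify.average_replicates(matrix, rep)

        paths["sjtpm_matrix"] = os.path.join(cfg.out_dir, "sjtpm_matrix.tsv")
        _stamped_tsv(matrix.sjtpm, paths["sjtpm_matrix"], cfg, index=True)
        paths["fractions"] = os.path.join(cfg.out_dir, "fractions.tsv")
        _stamped_tsv(matrix.fractions, paths["fractions"], cfg, index=True)

        paths["group_summary"] = os.path.join(cfg.out_dir, "group_summary.tsv")
        if cfg.group_key in matrix.meta.columns:
            summary = aggregate_groups(matrix, cfg.group_key)
        else:
            summary = pd.DataFrame(columns=["group", "variant", "mean", "sd", "n"])
        _stamped_tsv(summary, paths["group_summary"], cfg, index=False)

        paths["presence"] = os.path.join(cfg.out_dir, "presence.tsv")
        pres = presence_summary(matrix, cfg.detection_threshold).rename("n_samples_detected")
        _stamped_tsv(pres.to_frame(), paths["presence"], cfg, index=True)

        log.info("wrote %d tables to %s", len(paths), cfg.out_dir)
        return paths
    finally:
        root.removeHandler(handler)
        handler.close()
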