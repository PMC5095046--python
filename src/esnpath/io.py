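"""Readers and writers for the pipeline's exchange formats, plus run_all.

Tabular exchange is TSV (header row, UTF-8, no quoting), gene sets are GMT
(one set per line: name, description/database tag, tab-separated member
genes), ground truth and run manifests are JSON.  Floats are serialized at
repr round-trip precision ('%.17g') and all writers emit sorted,
deterministic output so identical inputs give byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .association import COVARIATE_NAMES, CohortData, run_association_scan
from .enrichment import (
    EnrichmentConfig,
    GeneSet,
    GeneSetCollection,
    fold_over_chance,
    run_enrichment,
    sensitivity_runner,
)
from .esnp import EQTL_COLUMNS, META_COLUMNS, validate_eqtl_table, validate_snp_metadata
from .simulate import SimulationConfig, SimulatedDataset, simulate_dataset

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_cohort",
    "write_cohort",
    "read_summary_stats",
    "write_summary_stats",
    "read_eqtl",
    "write_eqtl",
    "read_snp_meta",
    "write_snp_meta",
    "write_results",
    "write_truth",
    "RunManifest",
    "run_all",
    "file_digest",
]

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.17g"


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _to_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT, lineterminator="\n")


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def _check_numeric(df: pd.DataFrame, path: str | Path, cols: Sequence[str]) -> None:
    for c in cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[vals.isna() & df[c].notna()]
        if len(bad):
            raise ValueError(
                f"{path}: malformed numeric value in column {c!r} at row "
                f"{int(bad[0]) + 2}"  # +2: header line and 1-based count
            )
        df[c] = vals


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: per line, set name, description/db tag, members.

    Duplicate member ids within a line are collapsed with a warning;
    empty lines are skipped; duplicate set names or short lines raise.
    """
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name, tag, *members = fields
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            seen.add(name)
            uniq = list(dict.fromkeys(members))
            if len(uniq) < len(members):
                logger.warning(
                    "%s:%d: %d duplicate member id(s) collapsed in set %s",
                    path,
                    lineno,
                    len(members) - len(uniq),
                    name,
                )
            sets.append(GeneSet(name, tag, frozenset(uniq)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sorted(collection, key=lambda s: s.name):
            fh.write("\t".join([s.name, s.db_tag, *sorted(s.genes)]) + "\n")


# ---------------------------------------------------------------------------
# cohorts


def write_cohort(cohort: CohortData, path: str | Path) -> None:
    fixed = pd.DataFrame(
        {
            "sample_id": cohort.sample_ids,
            "study": cohort.study_id,
            "status": cohort.phenotype,
        }
    )
    cov = pd.DataFrame(cohort.covariates, columns=list(cohort.covariate_names))
    dose = pd.DataFrame(cohort.dosages, columns=cohort.snp_ids)
    _to_tsv(pd.concat([fixed, cov, dose], axis=1), path)


def read_cohort(path: str | Path) -> CohortData:
    fixed = ["sample_id", "study", "status", *COVARIATE_NAMES]
    df = _read_tsv(path, fixed)
    snp_cols = [c for c in df.columns if c not in fixed]
    _check_numeric(df, path, ["status", *COVARIATE_NAMES, *snp_cols])
    study = str(df["study"].iloc[0])
    return CohortData(
        study_id=study,
        sample_ids=df["sample_id"].astype(str).tolist(),
        phenotype=df["status"].to_numpy(),
        covariates=df[list(COVARIATE_NAMES)].to_numpy(dtype=float),
        dosages=df[snp_cols].to_numpy(dtype=float),
        snp_ids=snp_cols,
    )


# ---------------------------------------------------------------------------
# summary statistics / eQTL / metadata


def write_summary_stats(stats: pd.DataFrame, path: str | Path) -> None:
    df = stats.reset_index()
    _to_tsv(df.sort_values("snp_id", kind="mergesort"), path)


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, ["snp_id", "beta", "se", "p", "n_studies"])
    _check_numeric(df, path, ["beta", "se", "p", "n_studies"])
    if (df["p"] <= 0).any():
        raise ValueError(f"{path}: p-values must be > 0")
    return df.set_index("snp_id")


def write_eqtl(eqtl: pd.DataFrame, path: str | Path) -> None:
    _to_tsv(eqtl.sort_values(["snp_id", "gene_id"], kind="mergesort"), path)


def read_eqtl(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, EQTL_COLUMNS)
    _check_numeric(df, path, ["p_eqtl"])
    if (df["p_eqtl"] <= 0).any():
        bad = int(df.index[df["p_eqtl"] <= 0][0]) + 2
        raise ValueError(f"{path}: p_eqtl must be > 0 (row {bad})")
    return validate_eqtl_table(df)


def write_snp_meta(meta: pd.DataFrame, path: str | Path) -> None:
    _to_tsv(meta.sort_values("snp_id", kind="mergesort"), path)


def read_snp_meta(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, META_COLUMNS)
    _check_numeric(df, path, ["pos", "maf", "imp_r2"])
    return validate_snp_metadata(df)


def write_surrogates(surr: pd.DataFrame, path: str | Path) -> None:
    _to_tsv(surr.sort_values("gene_id", kind="mergesort"), path)


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    _to_tsv(results, path)


def write_truth(truth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_json_dict(), indent=2) + "\n")


# ---------------------------------------------------------------------------
# manifest and run_all


@dataclass
class RunManifest:
    """Bookkeeping of one pipeline run: seed, active thresholds, input
    digests, the count at each filtering stage (eSNPs identified ->
    available -> genes represented -> pathways tested -> nominal ->
    FDR-significant) and the fold-over-chance summary per database."""

    seed: int
    thresholds: dict[str, float]
    input_digests: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, int] = field(default_factory=dict)
    fold_over_chance: dict[str, dict[str, float]] = field(default_factory=dict)
    completed_stages: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "thresholds": self.thresholds,
                "input_digests": self.input_digests,
                "stage_counts": self.stage_counts,
                "fold_over_chance": self.fold_over_chance,
                "completed_stages": self.completed_stages,
            },
            indent=2,
            sort_keys=True,
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def write_dataset(data: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a simulated dataset to a directory; returns file paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for cohort in data.cohorts:
        p = out / f"cohort_{cohort.study_id}.tsv"
        write_cohort(cohort, p)
        paths[f"cohort_{cohort.study_id}"] = p
    paths["eqtl"] = out / "eqtl.tsv"
    write_eqtl(data.eqtl, paths["eqtl"])
    paths["snp_meta"] = out / "snp_meta.tsv"
    write_snp_meta(data.snp_meta, paths["snp_meta"])
    paths["gene_sets"] = out / "gene_sets.gmt"
    write_gmt(data.collection, paths["gene_sets"])
    paths["truth"] = out / "truth.json"
    write_truth(data.truth, paths["truth"])
    return paths


def run_all(
    sim_config: SimulationConfig,
    enr_config: EnrichmentConfig,
    out_dir: str | Path,
    sensitivity_thresholds: Sequence[float] | None = None,
) -> RunManifest:
    """Simulate -> associate -> select eSNPs -> enrich, writing every
    artifact (inputs, summary stats, surrogates, per-threshold results,
    manifest) under ``out_dir``.  On a stage failure the manifest still
    records the completed stages before the error propagates."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        seed=sim_config.seed,
        thresholds={
            "eqtl_threshold": enr_config.eqtl_threshold,
            "maf_min": enr_config.maf_min,
            "r2_min": enr_config.r2_min,
            "permutations": enr_config.permutations,
            "weight_p": enr_config.weight_p,
            "size_min": enr_config.size_min,
            "size_max": enr_config.size_max,
            "alpha": enr_config.alpha,
            "fdr_max": enr_config.fdr_max,
        },
    )
    try:
        data = simulate_dataset(sim_config)
        paths = write_dataset(data, out / "inputs")
        manifest.input_digests = {k: file_digest(p) for k, p in sorted(paths.items())}
        manifest.completed_stages.append("simulate")

        thresholds = list(sensitivity_thresholds or [enr_config.eqtl_threshold])
        per_threshold = sensitivity_runner(
            data.cohorts, data.eqtl, data.snp_meta, data.collection, thresholds, enr_config
        )
        manifest.completed_stages.append("enrich")
        for t, results in per_threshold.items():
            tag = f"{t:g}".replace("-", "m").replace("+", "")
            write_results(results, out / f"results_eqtl_{tag}.tsv")
            surr = pd.DataFrame(results.attrs["surrogates"])
            write_surrogates(surr, out / f"surrogates_eqtl_{tag}.tsv")
            if t == enr_config.eqtl_threshold:
                manifest.stage_counts = dict(results.attrs["stage_counts"])
                for tag_db in sorted(results["db_tag"].unique()):
                    sub = results[results["db_tag"] == tag_db]
                    n_sig = int((sub["p_perm"] < enr_config.alpha).sum())
                    f = fold_over_chance(n_sig, len(sub), enr_config.alpha)
                    manifest.fold_over_chance[str(tag_db)] = {
                        "n_tested": len(sub),
                        "n_nominal": n_sig,
                        "expected": f.expected,
                        "fold": f.fold,
                    }
        manifest.completed_stages.append("report")
    finally:
        manifest.write(out / "manifest.json")
    logger.info("run complete; stage counts: %s", manifest.stage_counts)
    return manifest
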