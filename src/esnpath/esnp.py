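"""eSNP selection, quality-control filtering and surrogate assignment.

An eSNP is a SNP whose genotype is associated with the expression of at
least one gene (here emulating skin-tissue eQTL summary statistics).  Genes
enter the pathway analysis through a single *surrogate* eSNP: among a gene's
eSNPs passing the eQTL significance threshold and the MAF / imputation-R^2
filters, the one most significantly associated with the disease.

Tabular containers are plain pandas DataFrames with documented columns:

* eQTL records: ``snp_id, gene_id, p_eqtl``
* SNP metadata: ``snp_id, chr, pos, maf, imp_r2``
* surrogates:   ``gene_id, snp_id, p_gwas, gene_statistic``

All threshold comparisons are strict (p_eqtl < t, maf > maf_min,
imp_r2 > r2_min); boundary rows are excluded.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "select_esnps",
    "apply_qc",
    "assign_surrogates",
    "validate_eqtl_table",
    "validate_snp_metadata",
]

logger = logging.getLogger(__name__)

EQTL_COLUMNS = ["snp_id", "gene_id", "p_eqtl"]
META_COLUMNS = ["snp_id", "chr", "pos", "maf", "imp_r2"]
DEFAULT_MAF_MIN = 0.01
DEFAULT_R2_MIN = 0.4


def validate_eqtl_table(eqtl: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in EQTL_COLUMNS if c not in eqtl.columns]
    if missing:
        raise ValueError(f"eQTL table missing columns: {missing}")
    p = eqtl["p_eqtl"].to_numpy(dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p_eqtl values must lie in (0, 1]")
    return eqtl


def validate_snp_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"SNP metadata missing columns: {missing}")
    if (meta["maf"] > 0.5).any() or (meta["maf"] <= 0).any():
        raise ValueError("maf must lie in (0, 0.5]")
    if (meta["pos"] < 1).any():
        raise ValueError("positions are 1-based; pos >= 1 required")
    return meta


def select_esnps(eqtl: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Rows with p_eqtl strictly below ``threshold``.

    A SNP regulating k genes contributes k rows; no deduplication is done
    here.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    validate_eqtl_table(eqtl)
    return eqtl.loc[eqtl["p_eqtl"] < threshold].copy()


def apply_qc(
    esnps: pd.DataFrame,
    meta: pd.DataFrame,
    maf_min: float = DEFAULT_MAF_MIN,
    r2_min: float = DEFAULT_R2_MIN,
    available_snps: set[str] | None = None,
) -> pd.DataFrame:
    """Filter eSNP records on MAF and imputation quality (strict bounds).

    Every eSNP must have a metadata row; missing rows raise with the
    offending ids.  When ``available_snps`` is given (the SNPs for which
    disease GWAS results exist), records for other SNPs are dropped with a
    logged count — the identified-versus-available bookkeeping step.
    """
    validate_snp_metadata(meta)
    meta_idx = meta.set_index("snp_id")
    unknown = sorted(set(esnps["snp_id"]) - set(meta_idx.index))
    if unknown:
        raise KeyError(f"eSNPs without metadata: {unknown}")
    maf = meta_idx["maf"].reindex(esnps["snp_id"]).to_numpy()
    r2 = meta_idx["imp_r2"].reindex(esnps["snp_id"]).to_numpy()
    keep = (maf > maf_min) & (r2 > r2_min)
    out = esnps.loc[keep].copy()
    if available_snps is not None:
        in_gwas = out["snp_id"].isin(available_snps)
        n_drop = int((~in_gwas).sum())
        if n_drop:
            logger.info(
                "dropping %d eSNP records for SNPs without GWAS results", n_drop
            )
        out = out.loc[in_gwas].copy()
    return out


def assign_surrogates(esnps: pd.DataFrame, gwas: pd.DataFrame) -> pd.DataFrame:
    """One surrogate eSNP per gene: the gene's eSNP with the smallest
    disease-association p-value (ties broken by lexicographically smallest
    snp_id).

    ``gwas`` is indexed by snp_id with a ``p`` column (the meta-analysis
    output).  Genes whose eSNPs all lack GWAS rows are absent from the
    result — pathways are only ever partially represented.  The ranking
    statistic is -log10(p_gwas).
    """
    tbl = esnps[["snp_id", "gene_id"]].copy()
    tbl["p_gwas"] = gwas["p"].reindex(tbl["snp_id"]).to_numpy()
    tbl = tbl.dropna(subset=["p_gwas"])
    if tbl.empty:
        return pd.DataFrame(columns=["gene_id", "snp_id", "p_gwas", "gene_statistic"])
    tbl = tbl.sort_values(["gene_id", "p_gwas", "snp_id"], kind="mergesort")
    best = tbl.groupby("gene_id", sort=True).head(1).reset_index(drop=True)
    best["gene_statistic"] = -np.log10(best["p_gwas"])
    return best[["gene_id", "snp_id", "p_gwas", "gene_statistic"]]
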