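"""Pathway enrichment over disease-ranked genes with a permutation null.

Genes enter through their surrogate eSNP's meta-analyzed disease p-value and
are ranked by r_j = -log10(p).  For a pathway S within a ranked list of N
genes (N_H hits, N_R = sum of hit weights r_j^p), a running sum gains
r_j^p / N_R at each hit and loses 1/(N - N_H) at each miss; the enrichment
score ES is the running-sum value of maximal absolute magnitude (signed).
This is the weighted Kolmogorov–Smirnov-like statistic of gene set
enrichment analysis, with weight exponent p = 1 by default.

Significance comes from phenotype-label permutations: case-control labels
are shuffled within each study, per-SNP association statistics are
recomputed by the covariate-adjusted score test, surrogate eSNPs are
re-selected, genes re-ranked, and every tested pathway re-scored.  ES values
are normalized sign-stratified by the mean same-sign permutation ES (NES),
and the false discovery rate is estimated from pooled permutation NES versus
observed NES, separately within each pathway database.  A pathway is called
significant at permutation p < 0.05 and FDR < 0.2.

Only pathways with between 3 and 200 member genes represented by surrogate
eSNPs (inclusive) are tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import CohortData, logistic_irls, run_association_scan, score_scan
from .esnp import apply_qc, assign_surrogates, select_esnps

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "RankedGeneList",
    "PermutationNull",
    "EnrichmentConfig",
    "FoldOverChance",
    "rank_genes",
    "enrichment_score",
    "permute_and_rescore",
    "permutation_p",
    "normalize_scores",
    "compute_fdr",
    "size_filter",
    "run_enrichment",
    "fold_over_chance",
    "sensitivity_runner",
]

DEFAULT_SIZE_MIN = 3
DEFAULT_SIZE_MAX = 200


@dataclass(frozen=True)
class GeneSet:
    name: str
    db_tag: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError(f"gene set {self.name!r} is empty")


class GeneSetCollection:
    """Named pathways with a database tag (KEGG / GO / BioCarta / custom)."""

    def __init__(self, sets: Iterable[GeneSet]):
        self.sets: dict[str, GeneSet] = {}
        for s in sets:
            if s.name in self.sets:
                raise ValueError(f"duplicate gene set name {s.name!r}")
            self.sets[s.name] = s

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def subset(self, names: Sequence[str]) -> "GeneSetCollection":
        return GeneSetCollection(self.sets[n] for n in names)

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for s in self:
            out |= s.genes
        return out


@dataclass
class RankedGeneList:
    """Genes ordered by descending ranking statistic (ties: gene id asc)."""

    genes: np.ndarray
    statistics: np.ndarray

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.statistics = np.asarray(self.statistics, dtype=float)
        if self.genes.shape != self.statistics.shape:
            raise ValueError("genes and statistics must align")
        if np.any(np.diff(self.statistics) > 0):
            raise ValueError("statistics must be non-increasing")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class PermutationNull:
    """Pathway-by-permutation matrix of null enrichment scores."""

    b: int
    pathways: list[str]
    es_null: np.ndarray
    seed: int

    def row(self, pathway: str) -> np.ndarray:
        return self.es_null[self.pathways.index(pathway)]


@dataclass
class EnrichmentConfig:
    """Knobs of the enrichment stage; defaults follow the reference analysis
    design (eQTL threshold 1e-5, MAF > 0.01, imputation R^2 > 0.4, 1,000
    label permutations, weight exponent 1, size filter 3–200)."""

    eqtl_threshold: float = 1e-5
    maf_min: float = 0.01
    r2_min: float = 0.4
    permutations: int = 1000
    weight_p: float = 1.0
    size_min: int = DEFAULT_SIZE_MIN
    size_max: int = DEFAULT_SIZE_MAX
    alpha: float = 0.05
    fdr_max: float = 0.2
    fdr_method: str = "gsea"  # or "bh"
    p_on: str = "es"  # or "nes"
    seed: int = 0


@dataclass
class FoldOverChance:
    expected: float
    fold: float


def rank_genes(surrogates: pd.DataFrame) -> RankedGeneList:
    """Order genes by descending gene_statistic; ties by gene id ascending."""
    if len(surrogates) == 0:
        raise ValueError("no surrogate genes to rank")
    tbl = surrogates.sort_values(
        ["gene_statistic", "gene_id"], ascending=[False, True], kind="mergesort"
    )
    return RankedGeneList(
        tbl["gene_id"].to_numpy(dtype=object),
        tbl["gene_statistic"].to_numpy(dtype=float),
    )


def _batch_es(
    stat_ordered: np.ndarray, member_ordered: np.ndarray, weight_p: float
) -> np.ndarray:
    """ES for each row of a pathway-by-gene boolean membership matrix whose
    columns follow the ranked gene order."""
    G = stat_ordered.shape[0]
    w = np.abs(stat_ordered) ** weight_p
    M = member_ordered
    nh = M.sum(axis=1)
    if np.any(nh == 0) or np.any(nh == G):
        raise ValueError("each pathway must hit a strict non-empty subset")
    nr = M @ w
    hit_inc = np.empty_like(M, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        hit_inc[:] = w[None, :] / nr[:, None]
    # degenerate: all hit weights zero -> uniform hit increments
    zero_rows = nr == 0
    if zero_rows.any():
        hit_inc[zero_rows] = (1.0 / nh[zero_rows])[:, None]
    dec = 1.0 / (G - nh)
    steps = np.where(M, hit_inc, -dec[:, None])
    cs = np.cumsum(steps, axis=1)
    j = np.argmax(np.abs(cs), axis=1)
    return cs[np.arange(cs.shape[0]), j]


def enrichment_score(
    ranked: RankedGeneList, members: set[str], weight_p: float = 1.0
) -> float:
    """Weighted KS-like running-sum enrichment score for one gene set."""
    hit = np.isin(ranked.genes, list(members))
    nh = int(hit.sum())
    if nh == 0:
        raise ValueError("gene set has no member in the ranked list")
    if nh == len(ranked):
        raise ValueError("gene set covers the entire ranked list; ES undefined")
    return float(_batch_es(ranked.statistics, hit[None, :], weight_p)[0])


def permutation_p(es_obs: float, es_null_row: np.ndarray) -> float:
    """Sign-agnostic permutation p with the (1 + count) / (1 + b) estimator."""
    row = np.asarray(es_null_row, dtype=float)
    if row.size == 0:
        raise ValueError("empty permutation null")
    count = int(np.sum(np.abs(row) >= abs(es_obs)))
    return (1 + count) / (1 + row.size)


def normalize_scores(
    es_obs: np.ndarray, es_null: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Sign-stratified normalization: positive ES divided by the mean
    positive null ES of the same pathway, negative ES by the mean |negative
    null ES|.  Pathways lacking same-sign null values get NaN with a
    warning."""
    es_obs = np.asarray(es_obs, dtype=float)
    es_null = np.asarray(es_null, dtype=float)
    P, b = es_null.shape
    pos_mean = np.full(P, np.nan)
    neg_mean = np.full(P, np.nan)
    for i in range(P):
        row = es_null[i]
        pos = row[row > 0]
        neg = row[row < 0]
        if pos.size:
            pos_mean[i] = pos.mean()
        if neg.size:
            neg_mean[i] = np.abs(neg).mean()

    def _norm(values: np.ndarray) -> np.ndarray:
        out = np.zeros_like(values, dtype=float)
        posv = values > 0
        negv = values < 0
        if values.ndim == 1:
            out[posv] = values[posv] / pos_mean[posv]
            out[negv] = values[negv] / neg_mean[negv]
        else:
            out[posv] = (values / pos_mean[:, None])[posv]
            out[negv] = (values / neg_mean[:, None])[negv]
        return out

    nes_obs = _norm(es_obs)
    nes_null = _norm(es_null)
    undefined = ((es_obs > 0) & ~np.isfinite(pos_mean)) | (
        (es_obs < 0) & ~np.isfinite(neg_mean)
    )
    if undefined.any():
        warnings.warn(
            f"NES undefined for {int(undefined.sum())} pathway(s): no same-sign "
            "permutation ES",
            RuntimeWarning,
            stacklevel=2,
        )
        nes_obs[undefined] = np.nan
    return nes_obs, nes_null


def compute_fdr(nes_obs: np.ndarray, nes_null: np.ndarray) -> np.ndarray:
    """GSEA-style FDR from pooled permutation NES, sign-stratified.

    For an observed nes*: numerator = fraction of pooled same-sign null NES
    at least as extreme in magnitude; denominator = fraction of observed
    same-sign NES at least as extreme.  The raw (uncapped) estimate is
    returned; cap at 1 for reporting.
    """
    nes_obs = np.asarray(nes_obs, dtype=float)
    pooled = np.asarray(nes_null, dtype=float).ravel()
    pooled = pooled[np.isfinite(pooled)]
    pos_pool = pooled[pooled > 0]
    neg_pool = np.abs(pooled[pooled < 0])
    finite = np.isfinite(nes_obs)
    pos_obs = nes_obs[finite & (nes_obs > 0)]
    neg_obs = np.abs(nes_obs[finite & (nes_obs < 0)])
    out = np.full(nes_obs.shape, np.nan)
    for i, v in enumerate(nes_obs):
        if not np.isfinite(v):
            continue
        if v > 0:
            pool, obs = pos_pool, pos_obs
        elif v < 0:
            pool, obs = neg_pool, neg_obs
        else:
            out[i] = 1.0
            continue
        a = np.abs(v)
        num = float(np.mean(pool >= a)) if pool.size else 0.0
        den = float(np.mean(obs >= a)) if obs.size else 0.0
        if den == 0:
            out[i] = 0.0 if num == 0 else 1.0
        else:
            out[i] = num / den
    return out


def size_filter(
    collection: GeneSetCollection,
    surrogates: pd.DataFrame,
    lo: int = DEFAULT_SIZE_MIN,
    hi: int = DEFAULT_SIZE_MAX,
) -> list[str]:
    """Names of pathways whose represented size (member genes possessing a
    surrogate eSNP) lies in [lo, hi], inclusive.  Sorted by name."""
    if lo > hi:
        raise ValueError("size_filter requires lo <= hi")
    represented = set(surrogates["gene_id"])
    names = []
    for s in collection:
        k = len(s.genes & represented)
        if lo <= k <= hi:
            names.append(s.name)
    return sorted(names)


# ---------------------------------------------------------------------------
# permutation engine


class _Workspace:
    """Precomputed structures shared by the observed pass and permutations:
    SNP-to-gene row grouping, represented genes, tested pathways and their
    membership matrix over the represented genes."""

    def __init__(
        self,
        cohorts: Sequence[CohortData],
        esnps: pd.DataFrame,
        collection: GeneSetCollection,
        size_min: int,
        size_max: int,
        weight_p: float,
    ):
        self.cohorts = list(cohorts)
        self.weight_p = weight_p
        rows = esnps[["snp_id", "gene_id"]].drop_duplicates()
        rows = rows.sort_values(["gene_id", "snp_id"], kind="mergesort")
        self.snp_union = sorted(rows["snp_id"].unique())
        snp_pos = {s: j for j, s in enumerate(self.snp_union)}
        self.row_snp = rows["snp_id"].map(snp_pos).to_numpy()
        gene_codes, genes = pd.factorize(rows["gene_id"], sort=True)
        self.genes = np.asarray(genes, dtype=object)
        # rows are gene-sorted so factorized codes are non-decreasing
        self.gene_starts = np.searchsorted(gene_codes, np.arange(len(genes)))
        represented = set(self.genes)
        self.tested = []
        for s in sorted(collection, key=lambda s: s.name):
            k = len(s.genes & represented)
            # a set covering every represented gene has no misses and an
            # undefined ES; such pathways are untestable and skipped
            if size_min <= k <= size_max and k < len(represented):
                self.tested.append(s)
        self.pathway_names = [s.name for s in self.tested]
        G = len(self.genes)
        gpos = {g: i for i, g in enumerate(self.genes)}
        self.member = np.zeros((len(self.tested), G), dtype=bool)
        for i, s in enumerate(self.tested):
            for g in s.genes:
                if g in gpos:
                    self.member[i, gpos[g]] = True
        # per-cohort dosage submatrices restricted to the SNP union
        self._D = []
        self._C = []
        self._mask = []
        for c in self.cohorts:
            present = np.array([c.has_snp(s) for s in self.snp_union])
            cols = [c._snp_index[s] for s, pr in zip(self.snp_union, present) if pr]
            self._D.append(np.ascontiguousarray(c.dosages[:, cols]))
            self._C.append(c.design_covariates())
            self._mask.append(np.where(present)[0])

    @property
    def n_pathways(self) -> int:
        return len(self.tested)

    def snp_p_from_labels(self, ys: Sequence[np.ndarray]) -> np.ndarray:
        """Meta-analyzed score-test p per SNP of the union given per-study
        phenotype vectors (observed or permuted)."""
        m = len(self.snp_union)
        U = np.zeros(m)
        V = np.zeros(m)
        for y, C, D, idx in zip(ys, self._C, self._D, self._mask):
            u, v = score_scan(y, C, D)
            U[idx] += u
            V[idx] += v
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = np.where(V > 0, U**2 / V, 0.0)
        p = stats.chi2.sf(chi2, df=1)
        return np.clip(p, np.nextafter(0, 1), 1.0)

    def gene_stats_from_snp_p(self, p_snp: np.ndarray) -> np.ndarray:
        """Surrogate selection under the ranking statistic: per gene, the
        minimum p over its eSNPs, mapped to -log10."""
        p_rows = p_snp[self.row_snp]
        p_gene = np.minimum.reduceat(p_rows, self.gene_starts)
        return -np.log10(p_gene)

    def es_from_gene_stats(self, stat: np.ndarray) -> np.ndarray:
        order = np.argsort(-stat, kind="stable")  # genes lexicographic => tie rule
        return _batch_es(stat[order], self.member[:, order], self.weight_p)


def permute_and_rescore(
    cohorts: Sequence[CohortData],
    esnps: pd.DataFrame,
    collection: GeneSetCollection,
    b: int,
    seed: int,
    weight_p: float = 1.0,
    size_min: int = DEFAULT_SIZE_MIN,
    size_max: int = DEFAULT_SIZE_MAX,
) -> PermutationNull:
    """Phenotype-permutation null of pathway enrichment scores.

    For each of ``b`` permutations, case-control labels are shuffled within
    each study (covariates stay attached to samples, so per-study case
    totals are conserved exactly), per-SNP association is recomputed by the
    covariate-adjusted score test, surrogate eSNPs are re-selected per gene,
    genes re-ranked, and the ES of every tested pathway recomputed.
    """
    if b < 1:
        raise ValueError("need at least one permutation")
    ws = _Workspace(cohorts, esnps, collection, size_min, size_max, weight_p)
    es_null = np.empty((ws.n_pathways, b))
    for t in range(b):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(t,)))
        ys = [rng.permutation(c.phenotype).astype(float) for c in ws.cohorts]
        p_snp = ws.snp_p_from_labels(ys)
        stat = ws.gene_stats_from_snp_p(p_snp)
        es_null[:, t] = ws.es_from_gene_stats(stat)
    return PermutationNull(b, ws.pathway_names, es_null, seed)


def fold_over_chance(
    n_significant: int, n_tested: int, alpha: float = 0.05
) -> FoldOverChance:
    """Observed nominally significant pathways relative to the alpha * n
    expected by chance."""
    if n_tested < 1:
        raise ValueError("n_tested must be >= 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    expected = alpha * n_tested
    return FoldOverChance(expected=expected, fold=n_significant / expected)


def _bh(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def run_enrichment(
    cohorts: Sequence[CohortData],
    eqtl: pd.DataFrame,
    snp_meta: pd.DataFrame,
    collection: GeneSetCollection,
    config: EnrichmentConfig | None = None,
) -> pd.DataFrame:
    """Full enrichment stage: eSNP selection -> QC -> association scan ->
    surrogate assignment -> ranking -> size filter -> observed ES ->
    permutation null -> NES -> FDR (per database) -> significance calls.

    Returns one row per tested pathway with columns pathway, db_tag,
    size_annotated, size_represented, es, nes, p_perm, fdr, fdr_raw,
    significant, sorted by (db_tag, p_perm, pathway).  Stage bookkeeping
    counts are attached in ``result.attrs["stage_counts"]``.
    """
    cfg = config or EnrichmentConfig()
    sel = select_esnps(eqtl, cfg.eqtl_threshold)
    available: set[str] = set()
    for c in cohorts:
        available |= set(c.snp_ids)
    qc = apply_qc(sel, snp_meta, cfg.maf_min, cfg.r2_min, available_snps=available)
    n_identified = sel["snp_id"].nunique()
    n_available = qc["snp_id"].nunique()
    if qc.empty:
        raise ValueError("no eSNPs survive selection and QC")
    scan = run_association_scan(cohorts, sorted(qc["snp_id"].unique()))
    usable = scan.index[np.isfinite(scan["p"].to_numpy())]
    qc = qc[qc["snp_id"].isin(set(usable))]
    surr = assign_surrogates(qc, scan)
    if surr.empty:
        raise ValueError("no genes with surrogate eSNPs")

    ws = _Workspace(cohorts, qc, collection, cfg.size_min, cfg.size_max, cfg.weight_p)
    if ws.n_pathways == 0:
        raise ValueError("no pathway passes the represented-size filter")
    # observed gene statistics, aligned to workspace gene order
    stat_map = dict(zip(surr["gene_id"], surr["gene_statistic"]))
    stat_obs = np.array([stat_map[g] for g in ws.genes], dtype=float)
    es_obs = ws.es_from_gene_stats(stat_obs)

    null = permute_and_rescore(
        cohorts,
        qc,
        collection,
        cfg.permutations,
        cfg.seed,
        cfg.weight_p,
        cfg.size_min,
        cfg.size_max,
    )
    assert null.pathways == ws.pathway_names
    nes_obs, nes_null = normalize_scores(es_obs, null.es_null)
    if cfg.p_on == "nes":
        base_obs, base_null = nes_obs, nes_null
    else:
        base_obs, base_null = es_obs, null.es_null
    p_perm = np.array(
        [
            permutation_p(base_obs[i], base_null[i])
            if np.isfinite(base_obs[i])
            else np.nan
            for i in range(ws.n_pathways)
        ]
    )

    db_tags = np.array([s.db_tag for s in ws.tested], dtype=object)
    fdr_raw = np.full(ws.n_pathways, np.nan)
    if cfg.fdr_method == "bh":
        for tag in np.unique(db_tags):
            idx = np.where(db_tags == tag)[0]
            fdr_raw[idx] = _bh(p_perm[idx])
    else:
        for tag in np.unique(db_tags):
            idx = np.where(db_tags == tag)[0]
            fdr_raw[idx] = compute_fdr(nes_obs[idx], nes_null[idx])
    fdr = np.minimum(fdr_raw, 1.0)

    represented = set(surr["gene_id"])
    significant = (p_perm < cfg.alpha) & (fdr < cfg.fdr_max)
    out = pd.DataFrame(
        {
            "pathway": ws.pathway_names,
            "db_tag": db_tags,
            "size_annotated": [len(s.genes) for s in ws.tested],
            "size_represented": [len(s.genes & represented) for s in ws.tested],
            "es": es_obs,
            "nes": nes_obs,
            "p_perm": p_perm,
            "fdr": fdr,
            "fdr_raw": fdr_raw,
            "significant": significant,
        }
    )
    out = out.sort_values(["db_tag", "p_perm", "pathway"], kind="mergesort").reset_index(
        drop=True
    )
    out.attrs["stage_counts"] = {
        "esnps_identified": int(n_identified),
        "esnps_available": int(n_available),
        "genes_represented": int(len(surr)),
        "pathways_tested": int(ws.n_pathways),
        "nominal_significant": int(np.nansum(p_perm < cfg.alpha)),
        "fdr_significant": int(significant.sum()),
    }
    out.attrs["surrogates"] = surr.to_dict(orient="list")
    return out


def sensitivity_runner(
    cohorts: Sequence[CohortData],
    eqtl: pd.DataFrame,
    snp_meta: pd.DataFrame,
    collection: GeneSetCollection,
    thresholds: Sequence[float],
    config: EnrichmentConfig | None = None,
) -> dict[float, pd.DataFrame]:
    """Re-run the full enrichment stage at each eQTL selection threshold with
    the same seed base, for sensitivity analysis of the eSNP cutoff."""
    if len(set(thresholds)) != len(thresholds):
        raise ValueError("thresholds must be distinct")
    cfg = config or EnrichmentConfig()
    out: dict[float, pd.DataFrame] = {}
    for t in thresholds:
        cfg_t = EnrichmentConfig(**{**cfg.__dict__, "eqtl_threshold": t})
        out[t] = run_enrichment(cohorts, eqtl, snp_meta, collection, cfg_t)
    return out
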