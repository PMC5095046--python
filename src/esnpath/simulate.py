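"""Synthetic multi-study case-control data with planted pathway effects.

The generator emulates the statistical structure the pipeline assumes: a
set of nested case-control studies of unbalanced case fraction, per-SNP
imputed dosages under Hardy–Weinberg genotype frequencies with imputation
noise, an eQTL summary table in which configurable fractions of SNPs are
eSNPs in three significance tiers, and gene-set collections in which chosen
pathways carry planted per-gene disease effects (log-odds per dosage unit,
placed on each causal gene's designated tier-1 eSNP).

Disease status follows a logistic model

    logit P(case) = alpha_s + sum_g beta_g * dosage(eSNP of g)
                    + gamma * (age - 60) + delta . PCs

with the study intercept alpha_s tuned by bisection so that the expected
case count matches the configured one.  SNPs are generated independently
(no linkage disequilibrium): the analysis consumes one surrogate eSNP per
gene, so inter-SNP correlation is not needed to exercise any stage.

Everything is a pure function of (config, seed): each stage draws from its
own seeded substream, so cohorts, eQTL table and gene sets are
bit-reproducible individually and jointly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .association import CohortData
from .enrichment import GeneSet, GeneSetCollection

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "SimulatedDataset",
    "simulate_cohorts",
    "simulate_eqtl_table",
    "simulate_gene_sets",
    "simulate_snp_metadata",
    "simulate_dataset",
    "default_gene_sets",
]

#: eQTL p-value interval per eSNP tier; tier 1 passes the strictest
#: selection threshold (1e-5), tier 2 enters at 5e-5, tier 3 at 1e-4.
TIER_INTERVALS = {1: (1e-7, 1e-5), 2: (1e-5, 5e-5), 3: (5e-5, 1e-4)}
NON_ESNP_INTERVAL = (1e-3, 1.0)

# default study design: eight nested case-control studies with unbalanced
# case fractions, totalling 2,323 cases and 7,275 controls
DEFAULT_SAMPLES = [
    (600, 1000),
    (400, 1400),
    (300, 800),
    (250, 1000),
    (250, 900),
    (200, 800),
    (180, 700),
    (143, 675),
]


class ConfigurationError(ValueError):
    pass


def default_gene_sets(
    n_genes: int, n_sets: int = 40, seed_sizes: Sequence[int] = (2, 250)
) -> list[tuple[str, str, int]]:
    """A default collection layout: mostly KEGG-tagged mid-size sets plus,
    where n_genes allows, one set below the size-3 filter and one above 200
    to exercise the boundaries."""
    rng = np.random.default_rng(12345)  # layout only; membership is seeded later
    sizes = rng.integers(5, 51, size=n_sets)
    out = [(f"PATH{i:03d}", "KEGG", int(s)) for i, s in enumerate(sizes)]
    if n_genes >= 3:
        out.append(("TINY_SET", "custom", min(seed_sizes)))
    if n_genes > max(seed_sizes):
        out.append(("HUGE_SET", "custom", max(seed_sizes)))
    return out


@dataclass
class SimulationConfig:
    """Full description of one synthetic dataset.

    ``esnp_fraction_per_threshold`` maps tier (1, 2, 3) to the fraction of
    SNPs that are eSNPs of that tier; ``planted_pathways`` lists
    (pathway name, per-gene log-odds per dosage unit).
    """

    n_studies: int = 8
    samples_per_study: list[tuple[int, int]] = field(
        default_factory=lambda: list(DEFAULT_SAMPLES)
    )
    n_snps: int = 5000
    n_genes: int = 500
    maf_range: tuple[float, float] = (0.05, 0.5)
    esnp_fraction_per_threshold: dict[int, float] = field(
        default_factory=lambda: {1: 0.20, 2: 0.05, 3: 0.03}
    )
    gene_sets: list[tuple[str, str, int]] | None = None
    planted_pathways: list[tuple[str, float]] = field(default_factory=list)
    imputation_r2_range: tuple[float, float] = (0.5, 1.0)
    age_effect: float = 0.02
    pc_effects: tuple[float, float, float] = (0.1, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies != len(self.samples_per_study):
            raise ConfigurationError("n_studies must match samples_per_study length")
        for nc, nk in self.samples_per_study:
            if nc < 1 or nk < 1:
                raise ConfigurationError("each study needs >= 1 case and >= 1 control")
        if self.n_snps < 1 or self.n_genes < 1:
            raise ConfigurationError("n_snps and n_genes must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        lo, hi = self.imputation_r2_range
        if not (0 < lo <= hi <= 1):
            raise ConfigurationError("imputation_r2_range must lie within (0, 1]")
        for t, f in self.esnp_fraction_per_threshold.items():
            if t not in TIER_INTERVALS:
                raise ConfigurationError(f"unknown eSNP tier {t}")
            if not (0 <= f <= 1):
                raise ConfigurationError("eSNP fractions must lie in [0, 1]")
        if sum(self.esnp_fraction_per_threshold.values()) > 1:
            raise ConfigurationError("eSNP fractions sum above 1")
        names = {n for n, _, _ in self.resolved_gene_sets()}
        for pname, _ in self.planted_pathways:
            if pname not in names:
                raise ConfigurationError(
                    f"planted pathway {pname!r} not among gene_sets"
                )
        for _, _, size in self.resolved_gene_sets():
            if size < 1:
                raise ConfigurationError("gene set sizes must be >= 1")
            if size > self.n_genes:
                raise ConfigurationError("gene set size exceeds n_genes")

    def resolved_gene_sets(self) -> list[tuple[str, str, int]]:
        if self.gene_sets is not None:
            return self.gene_sets
        return default_gene_sets(self.n_genes)


@dataclass
class SimulationTruth:
    """Ground truth of a simulated dataset, for test harnesses."""

    causal_genes: set[str]
    causal_pathways: set[str]
    effect_map: dict[str, float]
    esnp_map: dict[str, tuple[str, int]]
    causal_snp_map: dict[str, str] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "causal_genes": sorted(self.causal_genes),
            "causal_pathways": sorted(self.causal_pathways),
            "effect_map": dict(sorted(self.effect_map.items())),
            "esnp_map": {k: list(v) for k, v in sorted(self.esnp_map.items())},
            "causal_snp_map": dict(sorted(self.causal_snp_map.items())),
        }


@dataclass
class SimulatedDataset:
    cohorts: list[CohortData]
    truth: SimulationTruth
    eqtl: pd.DataFrame
    snp_meta: pd.DataFrame
    collection: GeneSetCollection


def _rng(config: SimulationConfig, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(key,)))


class _Plan:
    """Deterministic blueprint shared by all generator stages: SNP metadata,
    gene-set membership, eSNP-to-gene assignment and planted effects."""

    def __init__(self, config: SimulationConfig):
        self.config = config
        m, g = config.n_snps, config.n_genes
        width = max(4, len(str(m)))
        self.snp_ids = [f"rs{i:0{width}d}" for i in range(m)]
        gwidth = max(4, len(str(g)))
        self.gene_ids = [f"G{i:0{gwidth}d}" for i in range(g)]

        rng_meta = _rng(config, 0)
        lo, hi = config.maf_range
        self.maf = rng_meta.uniform(lo, hi, size=m)
        r_lo, r_hi = config.imputation_r2_range
        self.imp_r2 = rng_meta.uniform(r_lo, r_hi, size=m)
        self.chrom = 1 + (np.arange(m) % 22)
        self.pos = 10_000 + 1_000 * np.arange(m)

        rng_sets = _rng(config, 1)
        sets = []
        for name, tag, size in config.resolved_gene_sets():
            members = rng_sets.choice(g, size=size, replace=False)
            sets.append(
                GeneSet(name, tag, frozenset(self.gene_ids[i] for i in members))
            )
        self.collection = GeneSetCollection(sets)

        effect_map: dict[str, float] = {}
        causal_pathways = set()
        for pname, beta in config.planted_pathways:
            if beta == 0:
                continue
            causal_pathways.add(pname)
            for gene in self.collection[pname].genes:
                effect_map.setdefault(gene, beta)
        causal_genes = set(effect_map)

        rng_assign = _rng(config, 2)
        order = rng_assign.permutation(m)
        counts = {
            t: int(round(config.esnp_fraction_per_threshold.get(t, 0.0) * m))
            for t in (1, 2, 3)
        }
        if counts[1] < len(causal_genes):
            raise ConfigurationError(
                "tier-1 eSNP quota smaller than the number of causal genes"
            )
        if sum(counts.values()) > m:
            raise ConfigurationError("eSNP quotas exceed n_snps")
        esnp_map: dict[str, tuple[str, int]] = {}
        cursor = 0
        causal_sorted = sorted(causal_genes)
        for gene in causal_sorted:
            esnp_map[self.snp_ids[order[cursor]]] = (gene, 1)
            cursor += 1
        for tier in (1, 2, 3):
            remaining = counts[tier] - (len(causal_sorted) if tier == 1 else 0)
            for _ in range(max(remaining, 0)):
                gene = self.gene_ids[rng_assign.integers(g)]
                esnp_map[self.snp_ids[order[cursor]]] = (gene, tier)
                cursor += 1
        self.esnp_map = esnp_map
        # effect vector over SNPs: each causal gene's designated tier-1 eSNP
        # carries that gene's log-odds effect
        snp_pos = {s: j for j, s in enumerate(self.snp_ids)}
        self.beta_snp = np.zeros(m)
        self.causal_snp_of_gene: dict[str, str] = {}
        for snp, (gene, tier) in esnp_map.items():
            if gene in effect_map and gene not in self.causal_snp_of_gene:
                self.causal_snp_of_gene[gene] = snp
                self.beta_snp[snp_pos[snp]] = effect_map[gene]
        self.truth = SimulationTruth(
            causal_genes=causal_genes,
            causal_pathways=causal_pathways,
            effect_map=effect_map,
            esnp_map=esnp_map,
            causal_snp_map=dict(self.causal_snp_of_gene),
        )


def _tune_intercept(lp: np.ndarray, target: float) -> float:
    """Bisection on the study intercept so mean sigmoid(alpha + lp) hits the
    target case fraction."""
    lo, hi = -30.0, 30.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        frac = np.mean(0.5 * (1 + np.tanh(0.5 * (mid + lp))))
        if frac < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_cohorts(
    config: SimulationConfig,
) -> tuple[list[CohortData], SimulationTruth]:
    """Generate one CohortData per study plus the ground truth.

    Dosages: Hardy–Weinberg genotypes g ~ Binomial(2, maf) blended toward
    the mean with Gaussian noise so that the squared correlation between
    dosage and true genotype equals the SNP's imputation R^2; clipped to
    [0, 2].  Age ~ Normal(60, 8); PCs ~ Normal(0, 1), independent of
    genotype.
    """
    plan = _Plan(config)
    maf, r2 = plan.maf, plan.imp_r2
    mean_d = 2 * maf
    var_g = 2 * maf * (1 - maf)
    noise_sd = np.sqrt(np.maximum(r2 * (1 - r2) * var_g, 0.0))
    cohorts = []
    for s, (n_cases, n_controls) in enumerate(config.samples_per_study):
        n = n_cases + n_controls
        rng = _rng(config, 10 + s)
        g = rng.binomial(2, maf, size=(n, config.n_snps)).astype(float)
        d = mean_d + r2 * (g - mean_d) + rng.normal(0.0, 1.0, size=g.shape) * noise_sd
        np.clip(d, 0.0, 2.0, out=d)
        age = rng.normal(60.0, 8.0, size=n)
        pcs = rng.normal(0.0, 1.0, size=(n, 3))
        lp = (
            d @ plan.beta_snp
            + config.age_effect * (age - 60.0)
            + pcs @ np.asarray(config.pc_effects)
        )
        alpha = _tune_intercept(lp, n_cases / n)
        prob = 0.5 * (1 + np.tanh(0.5 * (alpha + lp)))
        y = rng.binomial(1, prob)
        if y.sum() == 0 or y.sum() == n:
            # pathological configs only; nudge one label to keep the cohort valid
            y[0] = 1 - y[0]
        study_id = f"study{s + 1}"
        cohorts.append(
            CohortData(
                study_id=study_id,
                sample_ids=[f"{study_id}_s{i:05d}" for i in range(n)],
                phenotype=y,
                covariates=np.column_stack([age, pcs]),
                dosages=d,
                snp_ids=list(plan.snp_ids),
            )
        )
    return cohorts, plan.truth


def simulate_eqtl_table(
    config: SimulationConfig, truth: SimulationTruth | None = None
) -> pd.DataFrame:
    """eQTL summary table: one row per SNP with its regulated gene and eQTL
    p-value.  Tiered eSNPs draw p uniformly from their tier interval;
    non-eSNPs draw from [1e-3, 1] and are attached to a random gene."""
    plan = _Plan(config)
    if truth is not None and truth.esnp_map != plan.truth.esnp_map:
        raise ValueError("truth does not match config (different seed or layout?)")
    rng = _rng(config, 3)
    rows = []
    for j, snp in enumerate(plan.snp_ids):
        if snp in plan.esnp_map:
            gene, tier = plan.esnp_map[snp]
            lo, hi = TIER_INTERVALS[tier]
        else:
            gene = plan.gene_ids[rng.integers(config.n_genes)]
            lo, hi = NON_ESNP_INTERVAL
        rows.append((snp, gene, rng.uniform(lo, hi)))
    return pd.DataFrame(rows, columns=["snp_id", "gene_id", "p_eqtl"])


def simulate_gene_sets(config: SimulationConfig) -> GeneSetCollection:
    """The gene-set collection implied by the config (deterministic)."""
    return _Plan(config).collection


def simulate_snp_metadata(config: SimulationConfig) -> pd.DataFrame:
    plan = _Plan(config)
    return pd.DataFrame(
        {
            "snp_id": plan.snp_ids,
            "chr": plan.chrom,
            "pos": plan.pos,
            "maf": plan.maf,
            "imp_r2": plan.imp_r2,
        }
    )


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Convenience bundle: cohorts, truth, eQTL table, SNP metadata and the
    gene-set collection, all from one config."""
    cohorts, truth = simulate_cohorts(config)
    return SimulatedDataset(
        cohorts=cohorts,
        truth=truth,
        eqtl=simulate_eqtl_table(config, truth),
        snp_meta=simulate_snp_metadata(config),
        collection=simulate_gene_sets(config),
    )
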