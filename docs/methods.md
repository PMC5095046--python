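# Methods

## The statistical procedure

`esnpath` implements an eSNP-integrated pathway analysis of a case-control
GWAS. The chain of operations is:

1. **eSNP selection.** From an eQTL summary table (SNP, gene, eQTL p-value,
   emulating published skin-tissue cis/trans eQTL results), keep records
   with `p_eqtl < t` for a configurable threshold `t` (default 1e-5; 5e-5
   and 1e-4 are the standard sensitivity settings). All comparisons are
   strict: a record at exactly the threshold is excluded. Records are then
   filtered on SNP quality: minor allele frequency strictly above 0.01 and
   imputation R² strictly above 0.4, and restricted to SNPs present in the
   disease GWAS.

2. **Per-study association.** In each nested case-control study, each SNP's
   dosage is tested against case status by multivariate logistic regression
   adjusted for age and the first three genetic principal components. The
   fit is iteratively reweighted least squares (Newton), maximum 50
   iterations, declared converged when the relative log-likelihood change
   falls below 1e-10; a tiny ridge (1e-12) stabilizes the Newton solve
   without affecting estimates at test tolerance. Constant dosages,
   non-convergence and quasi-separation (|β| > 15) are flagged and the
   study is dropped for that SNP rather than raising.

3. **Meta-analysis.** Study estimates are combined by fixed-effect
   inverse-variance weighting: β = Σwᵢβᵢ/Σwᵢ with wᵢ = 1/seᵢ²,
   se = (Σwᵢ)^(-1/2), two-sided normal p. No genomic-control correction and
   no random-effects model (the fixed-effect scheme is the convention for
   this design); heterogeneity statistics are out of scope.

4. **Surrogate eSNPs and gene ranking.** Each gene with at least one
   qualifying eSNP is represented by the eSNP with the smallest
   meta-analysis p (ties broken by lexicographically smallest SNP id, so
   output is independent of input order). The gene ranking statistic is
   r = −log10(p); this is monotone in the association chi-square and makes
   the weighted running sum scale-friendly. Genes are ranked by descending
   r, ties by gene id.

5. **Enrichment score.** For a pathway S in a ranked list of N genes
   (N_H = |S ∩ list|, N_R = Σ_{j∈S} r_j^p), a running sum gains r_j^p/N_R at
   each member gene and loses 1/(N−N_H) at each non-member; ES is the
   running-sum value of maximal absolute magnitude, signed. The weight
   exponent defaults to p = 1 and is configurable; p = 0 recovers the
   classic (unweighted) Kolmogorov–Smirnov statistic, which the tests
   verify against an independent two-sample KS computation.

6. **Permutation null.** Case-control labels are permuted within each study
   (covariates stay attached to samples, so per-study case totals and
   covariate distributions are conserved exactly); the default is 1,000
   permutations. Within each permutation the full statistic is recomputed:
   per-SNP association, surrogate re-selection, re-ranking, and ES for
   every tested pathway. Re-selecting surrogates inside the null matters —
   the per-gene minimum over eSNP p-values is part of the observed
   statistic, and freezing the observed surrogates would bias the null
   anti-conservatively.

7. **Fast path.** Refitting a full logistic regression per SNP in every
   permutation is needless: within a permutation the covariate-only null
   model is fitted once per study and a vectorized efficient-score
   statistic is computed for all SNPs at once (U = Dᵀ(y−p̂₀);
   V = DᵀWD − DᵀWC(CᵀWC)⁻¹CᵀWD; per-study U and V add across studies and
   χ² = U²/V). The observed-data pass always uses the full Wald logistic
   fit. Score and Wald tests are asymptotically equivalent; the suite
   asserts Spearman rank correlation > 0.99 between the two p-value sets on
   a null simulation.

8. **NES and FDR.** ES values are normalized sign-stratified: positive
   scores divide by the mean positive permutation ES of the same pathway,
   negative by the mean |negative ES|. A pathway with no same-sign
   permutation ES has undefined NES (reported as missing with a warning).
   The FDR of an observed nes* is the pooled-null estimate — the fraction
   of all permutation NES (same sign, pooled across pathways of the same
   database) at least as extreme, divided by the fraction of observed NES
   at least as extreme — reported raw (`fdr_raw`) and capped at 1 (`fdr`).
   FDR is computed within each pathway database (KEGG / GO / BioCarta /
   custom) separately, since each database defines its own testing
   universe. Benjamini–Hochberg on the permutation p-values is available
   behind `fdr_method="bh"` for comparison.

9. **Significance and reporting.** A pathway is called significant at
   permutation p < 0.05 and FDR < 0.2. Only pathways with 3–200 member
   genes *represented by surrogate eSNPs* (inclusive bounds) are tested; a
   pathway whose represented members cover the entire ranked list has no
   misses and an undefined ES, and is skipped. The permutation p-value uses
   the (1 + #{|ES_π| ≥ |ES|})/(1 + B) estimator, so the smallest reportable
   p at B = 1,000 is ≈ 0.001; it is strictly positive by construction. The
   p-value is sign-agnostic and ES-based by default (NES-based behind
   `p_on="nes"`). The fold-over-chance summary divides the count of
   nominally significant pathways by α·(number tested).

## Synthetic data

The generator produces the structure the analysis assumes, with known
ground truth:

* **Study design.** Default: eight case-control studies with unbalanced
  case fractions totalling 2,323 cases and 7,275 controls. Tests and the
  acceptance script use smaller explicit designs (two studies, 1,000–6,000
  samples) to keep runtimes at desk scale.
* **Dosages.** Per-SNP MAF uniform on `maf_range` (default 0.05–0.5);
  genotypes Binomial(2, MAF) under Hardy–Weinberg; imputation uncertainty
  mimicked by blending toward the mean plus Gaussian noise calibrated so
  corr²(dosage, genotype) equals the SNP's metadata R², then clipping to
  [0, 2] (clipping nudges the empirical R² slightly upward; the tests use
  a band accordingly). SNPs are independent — no LD is simulated, because
  the analysis consumes one surrogate eSNP per gene and inter-SNP
  correlation exercises no additional code path.
* **Phenotype.** logit P(case) = α_s + Σ_g β_g·dosage(eSNP of g) +
  γ(age−60) + δ·PCs with age ~ N(60, 8) and PCs ~ N(0, 1) independent of
  genotype (defaults γ = 0.02, δ = 0.1 each — nonzero so the covariate
  adjustment is exercised, but confounding-free). The study intercept α_s
  is tuned by bisection so the expected case count matches the configured
  one; realized counts are binomial around it.
* **eQTL table.** Configurable fractions of SNPs are eSNPs in three tiers,
  drawing eQTL p uniformly from [1e-7, 1e-5), [1e-5, 5e-5), [5e-5, 1e-4);
  non-eSNPs draw from [1e-3, 1]. Tier counts are exact (rounded fraction ×
  n_snps), so threshold bookkeeping is deterministic.
* **Planted effects.** Each gene of a planted pathway receives the
  configured log-odds effect on a dedicated tier-1 eSNP (a gene appearing
  in several planted pathways keeps its first-assigned effect). Effects are
  planted directly on the surrogate eSNP's dosage rather than through an
  expression intermediate; the joint distribution of expression and disease
  effects is not modelled, so the generator validates the testing machinery,
  not the biology of eQTL-mediated risk.
* **Determinism.** Every stage draws from its own substream of
  `SeedSequence(seed)`; identical config + seed reproduce cohorts, eQTL
  table and gene sets bit-for-bit, individually or jointly.

What the generator does *not* emulate: linkage disequilibrium, population
stratification (PCs are noise by default), X/Y chromosomes, trans-eQTL
distance structure, and correlated gene-set databases beyond random
overlap. Passing tests therefore demonstrate the statistical machinery is
correct and calibrated under the stated model, not that the pipeline is
robust to LD-induced SNP correlation or confounding in real cohorts.

## Numerical and design choices

* Strict inequalities at every threshold (eQTL p, MAF, R²); boundary
  behaviour is pinned by tests.
* Missing dosages are mean-imputed per SNP per study (dense-matrix dosage
  convention).
* p-values are floored at the smallest positive double so downstream
  −log10 never overflows; meta p is consistent with the normal
  approximation of β/se by construction.
* Problem sizes in tests and the acceptance script (2,000 SNPs / 400 genes
  / 40 pathways / 200 permutations for calibration; 1,200 SNPs / 6,000
  samples / 25 replicates for power) were chosen as the smallest designs
  at which the calibration and power properties are stable.
* Floats serialize at `%.17g` and tables are row-sorted before writing, so
  re-running a pipeline with the same config and seed yields byte-identical
  files; reading uses round-trip float parsing.

## Known limitations

* The permutation p floor is 1/(B+1); with B = 1,000 no pathway can report
  p below ≈ 0.001. Values printed as "<0.00001" in the literature for
  1,000-permutation analyses are not reproducible under this estimator and
  are not emulated.
* The score-test fast path agrees with the Wald observed pass in ranking
  (asserted), but individual permutation statistics are not identical to a
  full refit; this is the standard asymptotic trade.
* FDR estimates under few tested pathways and few permutations are coarse;
  `fdr_raw` can exceed 1 and is capped only for reporting.
* With very small pathways and non-negative ranking statistics, negative
  ES values occur but are rarely extreme; the sign-stratified machinery is
  general but mostly exercised on the positive branch.
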