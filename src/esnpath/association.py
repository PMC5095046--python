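"""Per-study SNP association and fixed-effect meta-analysis.

Each study is a nested case-control cohort: a binary phenotype, covariates
(age and the first three genetic principal components) and a sample-by-SNP
matrix of imputed allele dosages in [0, 2].  The observed-data pass fits a
multivariate logistic regression per SNP (dosage + covariates) by IRLS and
reports the Wald estimate; per-study estimates are then combined across
studies by inverse-variance-weighted (IVW) fixed-effect meta-analysis.

A covariate-adjusted score test is provided as a fast path for permutation
loops: the covariate-only null model is fitted once per (study, permutation)
and a vectorized score statistic is computed for every SNP at once.  Score
and Wald tests are asymptotically equivalent; their agreement is asserted in
the test suite rather than assumed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortData",
    "SnpAssociation",
    "StudyFit",
    "fit_study_association",
    "meta_analyze",
    "run_association_scan",
    "score_scan",
    "logistic_irls",
]

MAX_ITER = 50
LOGLIK_RTOL = 1e-10
SEPARATION_BETA = 15.0
COVARIATE_NAMES = ("age", "pc1", "pc2", "pc3")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # tanh form is stable for large |x|
    return 0.5 * (1.0 + np.tanh(0.5 * x))


@dataclass
class CohortData:
    """One case-control study: phenotype, covariates and dosage matrix.

    ``covariates`` has one column per entry of ``covariate_names`` (by
    default age, pc1..pc3); an intercept is added internally and must not
    be included.  Dosages are expected allele counts in [0, 2]; missing
    values (NaN) are mean-imputed per SNP on validation, the standard
    dosage-file convention.
    """

    study_id: str
    sample_ids: list[str]
    phenotype: np.ndarray
    covariates: np.ndarray
    dosages: np.ndarray
    snp_ids: list[str]
    covariate_names: tuple[str, ...] = COVARIATE_NAMES

    def __post_init__(self) -> None:
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        self.covariates = np.asarray(self.covariates, dtype=float)
        self.dosages = np.asarray(self.dosages, dtype=float)
        n = self.phenotype.shape[0]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids and phenotype length mismatch")
        if self.covariates.shape[0] != n or self.dosages.shape[0] != n:
            raise ValueError("covariates/dosages must share the sample dimension")
        if self.covariates.shape[1] != len(self.covariate_names):
            raise ValueError("covariate matrix width does not match covariate_names")
        if self.dosages.shape[1] != len(self.snp_ids):
            raise ValueError("dosage matrix width does not match snp_ids")
        if not set(np.unique(self.phenotype)) <= {0, 1}:
            raise ValueError("phenotype must be binary 0/1")
        if self.phenotype.sum() == 0 or self.phenotype.sum() == n:
            raise ValueError(f"study {self.study_id}: needs at least one case and one control")
        if np.isnan(self.dosages).any():
            col_mean = np.nanmean(self.dosages, axis=0)
            idx = np.where(np.isnan(self.dosages))
            self.dosages[idx] = np.take(col_mean, idx[1])
        if self.dosages.min() < -1e-9 or self.dosages.max() > 2 + 1e-9:
            raise ValueError("dosage values must lie in [0, 2]")
        self._snp_index = {s: j for j, s in enumerate(self.snp_ids)}

    @property
    def n_samples(self) -> int:
        return self.phenotype.shape[0]

    @property
    def n_cases(self) -> int:
        return int(self.phenotype.sum())

    def design_covariates(self) -> np.ndarray:
        """Covariate design matrix with a leading intercept column."""
        n = self.n_samples
        return np.column_stack([np.ones(n), self.covariates])

    def snp_column(self, snp_id: str) -> np.ndarray:
        try:
            return self.dosages[:, self._snp_index[snp_id]]
        except KeyError:
            raise KeyError(f"SNP {snp_id!r} not present in study {self.study_id}") from None

    def has_snp(self, snp_id: str) -> bool:
        return snp_id in self._snp_index


@dataclass
class StudyFit:
    """Per-study logistic fit for a single SNP."""

    beta: float
    se: float
    p: float
    converged: bool
    valid: bool
    reason: str = ""


@dataclass
class SnpAssociation:
    """Meta-analyzed disease association for one SNP."""

    snp_id: str
    beta: float
    se: float
    p: float
    n_studies: int

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("se must be positive")
        if not (0 < self.p <= 1):
            raise ValueError("p must lie in (0, 1]")


def logistic_irls(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = MAX_ITER,
    rtol: float = LOGLIK_RTOL,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Maximum-likelihood logistic regression by iteratively reweighted LS.

    Returns (beta, covariance, converged).  Convergence is declared when the
    relative change in log-likelihood drops below ``rtol``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    beta = np.zeros(k)
    ybar = y.mean()
    if 0 < ybar < 1:
        beta[0] = np.log(ybar / (1 - ybar)) if np.allclose(X[:, 0], 1.0) else 0.0
    ll_old = -np.inf
    converged = False
    eye = np.eye(k)
    for _ in range(max_iter):
        eta = X @ beta
        p = _sigmoid(eta)
        w = np.clip(p * (1 - p), 1e-12, None)
        grad = X.T @ (y - p)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H + 1e-12 * eye, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        eta = X @ beta
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        if (
            np.isfinite(ll)
            and np.isfinite(ll_old)
            and abs(ll - ll_old) <= rtol * (abs(ll_old) + 1e-30)
        ):
            converged = True
            break
        ll_old = ll
    eta = X @ beta
    p = _sigmoid(eta)
    w = np.clip(p * (1 - p), 1e-12, None)
    H = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(H + 1e-12 * eye)
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
        converged = False
    return beta, cov, converged


def fit_study_association(cohort: CohortData, snp_id: str) -> StudyFit:
    """Logistic regression of case status on one SNP's dosage plus covariates.

    Constant dosage, perfect separation (|beta| above the separation guard)
    and non-convergence yield a flagged result (``valid=False``) that the
    meta-analysis skips; they never raise.
    """
    d = cohort.snp_column(snp_id)
    if np.std(d) == 0:
        return StudyFit(np.nan, np.nan, np.nan, False, False, "constant dosage")
    X = np.column_stack([cohort.design_covariates(), d])
    beta, cov, converged = logistic_irls(X, cohort.phenotype)
    b = float(beta[-1])
    se = float(np.sqrt(cov[-1, -1])) if np.isfinite(cov[-1, -1]) else np.nan
    if not converged or not np.isfinite(b) or not np.isfinite(se) or se <= 0:
        return StudyFit(b, se, np.nan, False, False, "non-convergence")
    if abs(b) > SEPARATION_BETA:
        return StudyFit(b, se, np.nan, converged, False, "separation")
    p = float(2 * stats.norm.sf(abs(b / se)))
    return StudyFit(b, se, max(p, np.nextafter(0, 1)), True, True)


def meta_analyze(
    per_study: Sequence[tuple[float, float]], snp_id: str = ""
) -> SnpAssociation:
    """Fixed-effect inverse-variance-weighted combination of study estimates.

    beta = sum(w_i b_i) / sum(w_i), w_i = 1/se_i^2; se = sqrt(1/sum(w_i));
    two-sided normal p-value on beta/se.
    """
    if len(per_study) == 0:
        raise ValueError("meta_analyze requires at least one study result")
    betas = np.array([b for b, _ in per_study], dtype=float)
    ses = np.array([s for _, s in per_study], dtype=float)
    if np.any(ses <= 0) or np.any(~np.isfinite(ses)):
        raise ValueError("all standard errors must be positive and finite")
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    p = float(2 * stats.norm.sf(abs(beta / se)))
    return SnpAssociation(snp_id, beta, se, max(p, np.nextafter(0, 1)), len(per_study))


# ---------------------------------------------------------------------------
# vectorized per-SNP logistic scan


def _scan_study(
    y: np.ndarray, C: np.ndarray, D: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit one logistic regression per column of D (covariates C shared).

    Newton iterations are carried out jointly for all SNPs; each SNP has its
    own (k+1)-parameter model differing only in the dosage column.  Returns
    (beta, se, valid) arrays of length m.
    """
    n, k = C.shape
    m = D.shape[1]
    variable = D.std(axis=0) > 0
    kk = k + 1
    B = np.zeros((m, kk))
    ybar = y.mean()
    B[:, 0] = np.log(ybar / (1 - ybar))
    ll_old = np.full(m, -np.inf)
    active = variable.copy()
    eye = np.eye(kk) * 1e-12
    for _ in range(MAX_ITER):
        if not active.any():
            break
        eta = C @ B[:, :k].T + D * B[:, k]  # (n, m)
        P = _sigmoid(eta)
        W = np.clip(P * (1 - P), 1e-12, None)
        R = y[:, None] - P
        g_c = C.T @ R  # (k, m)
        g_d = np.einsum("nm,nm->m", D, R)
        H_cc = np.einsum("nk,nm,nl->mkl", C, W, C)
        WD = W * D
        H_cd = C.T @ WD  # (k, m)
        H_dd = np.einsum("nm,nm->m", WD, D)
        H = np.empty((m, kk, kk))
        H[:, :k, :k] = H_cc
        H[:, :k, k] = H_cd.T
        H[:, k, :k] = H_cd.T
        H[:, k, k] = H_dd
        grad = np.empty((m, kk))
        grad[:, :k] = g_c.T
        grad[:, k] = g_d
        idx = np.where(active)[0]
        try:
            step = np.linalg.solve(H[idx] + eye, grad[idx][..., None])[..., 0]
        except np.linalg.LinAlgError:
            break
        B[idx] += step
        eta = C @ B[:, :k].T + D * B[:, k]
        ll = y @ eta - np.logaddexp(0.0, eta).sum(axis=0)
        done = np.isfinite(ll_old) & (
            np.abs(ll - ll_old) <= LOGLIK_RTOL * (np.abs(ll_old) + 1e-30)
        )
        ll_old = ll
        active &= ~done
    eta = C @ B[:, :k].T + D * B[:, k]
    P = _sigmoid(eta)
    W = np.clip(P * (1 - P), 1e-12, None)
    H_cc = np.einsum("nk,nm,nl->mkl", C, W, C)
    WD = W * D
    H_cd = C.T @ WD
    H_dd = np.einsum("nm,nm->m", WD, D)
    H = np.empty((m, kk, kk))
    H[:, :k, :k] = H_cc
    H[:, :k, k] = H_cd.T
    H[:, k, :k] = H_cd.T
    H[:, k, k] = H_dd
    try:
        cov = np.linalg.inv(H + eye)
        se = np.sqrt(np.maximum(cov[:, k, k], 0.0))
    except np.linalg.LinAlgError:
        se = np.full(m, np.nan)
    beta = B[:, k]
    valid = (
        variable
        & ~active
        & np.isfinite(beta)
        & np.isfinite(se)
        & (se > 0)
        & (np.abs(beta) <= SEPARATION_BETA)
    )
    return beta, se, valid


def run_association_scan(
    cohorts: Sequence[CohortData], snp_ids: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-SNP meta-analyzed association across studies.

    Fits the full per-SNP logistic model in every study where the SNP is
    present and non-degenerate, then combines by IVW.  A SNP missing from a
    study (or flagged there) simply loses that study; a SNP absent from all
    studies raises.  Returns a DataFrame indexed by snp_id with columns
    beta, se, p, n_studies.
    """
    if len(cohorts) == 0:
        raise ValueError("no cohorts supplied")
    if snp_ids is None:
        seen: dict[str, None] = {}
        for c in cohorts:
            for s in c.snp_ids:
                seen.setdefault(s, None)
        snp_ids = list(seen)
    snp_ids = list(snp_ids)
    missing_everywhere = [s for s in snp_ids if not any(c.has_snp(s) for c in cohorts)]
    if missing_everywhere:
        raise ValueError(f"SNPs absent from all cohorts: {missing_everywhere}")

    m = len(snp_ids)
    sum_w = np.zeros(m)
    sum_wb = np.zeros(m)
    n_st = np.zeros(m, dtype=int)
    for c in cohorts:
        present = np.array([c.has_snp(s) for s in snp_ids])
        if not present.any():
            continue
        cols = [c._snp_index[s] for s, pr in zip(snp_ids, present) if pr]
        D = c.dosages[:, cols]
        C = c.design_covariates()
        beta, se, valid = _scan_study(c.phenotype.astype(float), C, D)
        w = np.zeros_like(beta)
        w[valid] = 1.0 / se[valid] ** 2
        pidx = np.where(present)[0]
        sum_w[pidx] += w
        sum_wb[pidx] += w * np.where(valid, beta, 0.0)
        n_st[pidx] += valid.astype(int)

    with np.errstate(divide="ignore", invalid="ignore"):
        beta_meta = sum_wb / sum_w
        se_meta = np.sqrt(1.0 / sum_w)
        z = beta_meta / se_meta
    p = 2 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    out = pd.DataFrame(
        {"beta": beta_meta, "se": se_meta, "p": p, "n_studies": n_st},
        index=pd.Index(snp_ids, name="snp_id"),
    )
    out.loc[n_st == 0, ["beta", "se", "p"]] = np.nan
    return out


def score_scan(
    y: np.ndarray, C: np.ndarray, D: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Covariate-adjusted score test pieces for every SNP column of D.

    Fits the covariate-only logistic null once, then returns the efficient
    score U_j and its variance V_j for each SNP j; the score chi-square is
    U^2/V and per-study (U, V) add across studies for a combined test.
    """
    y = np.asarray(y, dtype=float)
    beta0, _, _ = logistic_irls(C, y)
    p0 = _sigmoid(C @ beta0)
    w = np.clip(p0 * (1 - p0), 1e-12, None)
    r = y - p0
    U = D.T @ r
    CW = C * w[:, None]
    G = C.T @ CW
    A = CW.T @ D  # (k, m)
    try:
        GA = np.linalg.solve(G, A)
    except np.linalg.LinAlgError:
        GA = np.linalg.lstsq(G, A, rcond=None)[0]
    V = np.einsum("nm,nm->m", w[:, None] * D, D) - np.einsum("km,km->m", A, GA)
    return U, np.maximum(V, 0.0)
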