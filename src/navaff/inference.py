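"""Statistical machinery for comparing RDMs.

Implements rank-correlation RSA between dissimilarity matrices, condition-level
bootstrap resampling (90% subsampling without replacement, so that the unused
RDM diagonal never enters a resample), row/column permutation tests with the
one-tailed p-value

    p = (#{R_perm >= R_test} + 1) / (N + 1),

Bonferroni correction, subject-to-group noise ceilings, multiple-regression
RSA on vectorized RDMs, and commonality analysis: the decomposition of a
two-predictor regression's R^2 into unique and common parts,

    gamma1 = R2_12 - R2_2          (unique to X1)
    gamma2 = R2_12 - R2_1          (unique to X2)
    gamma12 = R2_1 + R2_2 - R2_12  (common to X1 and X2)
    SV = 100 * gamma12 / (gamma12 + gamma1),

where SV is the percentage of X1's explained variance in the target that is
shared with X2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._utils import rng_from
from .rdm import RDM, group_rdm

__all__ = [
    "CommonalityResult",
    "InferenceResult",
    "NoiseCeiling",
    "RegressionRSAResult",
    "bonferroni",
    "bootstrap_se",
    "bootstrap_sv_contrast",
    "commonality",
    "noise_ceiling",
    "permutation_test",
    "regression_rsa",
    "spearman_rsa",
]


@dataclass
class InferenceResult:
    statistic: float
    bootstrap_se: float | None = None
    p_value: float | None = None
    p_corrected: float | None = None
    n_iterations: int | None = None
    resample_fraction: float | None = None
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class RegressionRSAResult:
    r2: float
    coefficients: np.ndarray  # intercept last
    n_pairs: int


@dataclass
class CommonalityResult:
    r2_full: float
    r2_x1: float
    r2_x2: float
    gamma1: float
    gamma2: float
    gamma12: float
    shared_variance_pct: float
    sv_defined: bool = True


@dataclass
class NoiseCeiling:
    value: float
    per_subject: tuple[float, ...]


def _check_pair(rdm_a: RDM, rdm_b: RDM, min_n: int = 4) -> None:
    if rdm_a.labels != rdm_b.labels:
        raise ValueError("RDMs must share labels in the same order")
    if rdm_a.n_conditions < min_n:
        raise ValueError(f"need at least {min_n} conditions")


def spearman_rsa(rdm_a: RDM, rdm_b: RDM) -> float:
    """Spearman rank correlation of the two upper-triangle distance vectors.

    Ties receive average ranks.  Returns NaN when either vector is constant
    (the correlation is undefined there); callers treat NaN as a flagged,
    degenerate result.
    """
    _check_pair(rdm_a, rdm_b)
    va, vb = rdm_a.vector(), rdm_b.vector()
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        return float("nan")
    rho = stats.spearmanr(va, vb).statistic
    return float(rho)


def bootstrap_se(
    rdm_a: RDM,
    rdm_b: RDM,
    statistic_fn=spearman_rsa,
    n_iterations: int = 5000,
    fraction: float = 0.90,
    seed: int = 0,
) -> float:
    """Bootstrap SE of an RDM-comparison statistic by condition subsampling.

    Each iteration draws the same subset of round(fraction * n) conditions
    (without replacement) from both RDMs and recomputes the statistic; the SE
    is the standard deviation over iterations.  Subsampling without
    replacement avoids ever selecting a condition twice, which would place
    diagonal (self-comparison) zeros into the distance vectors.
    """
    _check_pair(rdm_a, rdm_b)
    n = rdm_a.n_conditions
    size = int(round(fraction * n))
    if size < 4:
        raise ValueError(f"subset size {size} < 4; increase fraction or n")
    rng = rng_from(seed)
    vals = np.empty(n_iterations)
    for i in range(n_iterations):
        idx = rng.choice(n, size=size, replace=False)
        vals[i] = statistic_fn(rdm_a.subset(idx), rdm_b.subset(idx))
    return float(np.std(vals, ddof=1))


def permutation_test(
    rdm_a: RDM,
    rdm_b: RDM,
    n_iterations: int = 5000,
    seed: int = 0,
    statistic_fn=spearman_rsa,
) -> InferenceResult:
    """One-tailed condition-permutation test of an RDM correlation.

    Rows and columns of ``rdm_b`` are permuted jointly by a single condition
    permutation per iteration; the minimum attainable p is 1/(N+1).
    """
    _check_pair(rdm_a, rdm_b)
    r_test = statistic_fn(rdm_a, rdm_b)
    n = rdm_a.n_conditions
    rng = rng_from(seed)
    labels = rdm_b.labels
    exceed = 0
    for _ in range(n_iterations):
        perm = rng.permutation(n)
        permuted = RDM(rdm_b.values[np.ix_(perm, perm)], labels, source=rdm_b.source)
        if statistic_fn(rdm_a, permuted) >= r_test:
            exceed += 1
    p = (exceed + 1) / (n_iterations + 1)
    return InferenceResult(
        statistic=r_test, p_value=p, n_iterations=n_iterations,
        degenerate=bool(np.isnan(r_test)),
    )


def bonferroni(p_values, m: int | None = None) -> list[float]:
    """Multiply each p by the number of comparisons m, capping at 1."""
    p_values = list(p_values)
    if m is None:
        m = len(p_values)
    if m < len(p_values):
        raise ValueError("m must be >= number of p-values")
    return [min(1.0, p * m) for p in p_values]


def noise_ceiling(subject_rdms: list[RDM]) -> NoiseCeiling:
    """Mean Spearman correlation of each subject-level RDM to the group mean.

    The group RDM is the mean over all subjects, with the subject included
    (not leave-one-out); the resulting ceiling is the expected RSA correlation
    of a model that predicts like the average subject.
    """
    if len(subject_rdms) < 2:
        raise ValueError("noise ceiling requires at least two subjects")
    grp = group_rdm(subject_rdms)
    per = tuple(spearman_rsa(s, grp) for s in subject_rdms)
    return NoiseCeiling(value=float(np.mean(per)), per_subject=per)


def _design_matrix(predictors: list[RDM]) -> np.ndarray:
    cols = [p.vector() for p in predictors]
    x = np.column_stack(cols + [np.ones_like(cols[0])])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError(
            "perfectly collinear predictors (design matrix is rank deficient)"
        )
    return x


def _ols_fit(target: RDM, predictors: list[RDM]) -> RegressionRSAResult:
    y = target.vector()
    cols = [p.vector() for p in predictors]
    x = np.column_stack(cols + [np.ones_like(cols[0])])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("target distance vector is constant")
    r2 = 1.0 - np.sum(resid**2) / ss_tot
    return RegressionRSAResult(r2=float(r2), coefficients=beta, n_pairs=len(y))


def regression_rsa(target: RDM, predictors: list[RDM]) -> RegressionRSAResult:
    """OLS fit of the target distance vector on predictor distance vectors.

    An intercept column is always appended.  Returns the coefficient vector
    (predictors first, intercept last) and the coefficient of determination.
    Perfectly collinear predictors are an error here (the coefficients would
    be unidentifiable); commonality analysis, which only needs R^2 values,
    tolerates duplicate predictors.
    """
    if not predictors:
        raise ValueError("need at least one predictor RDM")
    for p in predictors:
        _check_pair(target, p)
    _design_matrix(predictors)  # collinearity check
    return _ols_fit(target, predictors)


def commonality(target: RDM, x1: RDM, x2: RDM) -> CommonalityResult:
    """Two-predictor commonality (variance-partitioning) analysis.

    Fits the three OLS models (X1; X2; X1+X2) on the vectorized RDMs and
    decomposes the full model's R^2.  When X1 explains nothing at all
    (gamma12 + gamma1 = R2_1 = 0) the shared-variance percentage is undefined
    and flagged rather than returned as NaN arithmetic downstream.
    """
    for p in (x1, x2):
        _check_pair(target, p)
    r2_1 = _ols_fit(target, [x1]).r2
    r2_2 = _ols_fit(target, [x2]).r2
    r2_12 = _ols_fit(target, [x1, x2]).r2
    g1 = r2_12 - r2_2
    g2 = r2_12 - r2_1
    g12 = r2_1 + r2_2 - r2_12
    denom = g12 + g1  # algebraically equals r2_1
    if abs(denom) < 1e-14:
        return CommonalityResult(r2_12, r2_1, r2_2, g1, g2, g12, float("nan"), False)
    return CommonalityResult(r2_12, r2_1, r2_2, g1, g2, g12, 100.0 * g12 / denom, True)


def bootstrap_sv_contrast(
    target: RDM,
    x1: RDM,
    x2_a: RDM,
    x2_b: RDM,
    n_iterations: int = 5000,
    fraction: float = 0.90,
    seed: int = 0,
) -> dict:
    """Bootstrap contrast of two shared-variance scores, SV(x2_a) - SV(x2_b).

    Conditions are resampled jointly across all four RDMs (without
    replacement, 90% subsets); the reported bound is the 5th percentile of the
    difference distribution, i.e. the lower limit of a one-tailed 95%
    confidence interval.  ``significant`` is True when that bound exceeds 0.
    """
    for p in (x1, x2_a, x2_b):
        _check_pair(target, p)
    n = target.n_conditions
    size = int(round(fraction * n))
    if size < 4:
        raise ValueError(f"subset size {size} < 4")
    rng = rng_from(seed)
    diffs = np.empty(n_iterations)
    for i in range(n_iterations):
        idx = rng.choice(n, size=size, replace=False)
        sv_a = commonality(target.subset(idx), x1.subset(idx), x2_a.subset(idx))
        sv_b = commonality(target.subset(idx), x1.subset(idx), x2_b.subset(idx))
        diffs[i] = sv_a.shared_variance_pct - sv_b.shared_variance_pct
    lower = float(np.percentile(diffs, 5.0))
    return {
        "lower_95_one_tailed": lower,
        "significant": bool(lower > 0),
        "mean_difference": float(np.mean(diffs)),
        "n_iterations": n_iterations,
    }
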