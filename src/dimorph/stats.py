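"""Statistical primitives for the dimorphism pipelines.

Implements bias-reduced (Firth-type) logistic regression and its
likelihood-ratio test, the stratified exact one-sided Cochran–Mantel–
Haenszel mid-p test with its minimal-attainable-p ("alpha star") filters,
step-up multiplicity adjustment, the Newcombe score interval for a
difference of proportions, effect standardization, and the Jaccard set
statistic.

Everything here is pure computation: no file I/O, deterministic given its
inputs.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "FitResult",
    "TestOutcome",
    "Interval",
    "StratumTable",
    "firth_logistic_fit",
    "firth_lr_test",
    "cmh_midp_onesided",
    "cmh_null_distribution",
    "mh_alpha_star",
    "lrko_alpha_star",
    "multiplicity_adjust",
    "newcombe_diff_ci",
    "standardize_effect",
    "jaccard_similarity",
]


@dataclass
class FitResult:
    """A fitted model: coefficients, uncertainty and provenance.

    ``log_likelihood`` is the Jeffreys-penalized log-likelihood for
    bias-reduced logistic fits and the ML log-likelihood for mixed fits.
    """

    estimates: dict[str, float]
    standard_errors: dict[str, float]
    log_likelihood: float
    converged: bool
    n_obs: int
    method: str = ""
    residual_structure: str | None = None
    variance_components: dict[str, float] = field(default_factory=dict)
    aic: float | None = None
    n_fixed: int = 0
    fingerprint: tuple = ()
    flags: list[str] = field(default_factory=list)


@dataclass
class TestOutcome:
    statistic: float
    df: int
    p_value: float
    sidedness: str = "two_sided"
    method: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


@dataclass
class Interval:
    point: float
    lower: float
    upper: float
    level: float = 0.95

    def excludes_zero(self) -> bool:
        return self.lower > 0.0 or self.upper < 0.0


@dataclass
class StratumTable:
    """One sex stratum of abnormal-count data: control and mutant cells."""

    stratum: str
    control: tuple[int, int]  # (n_abnormal, n_total)
    mutant: tuple[int, int]

    def __post_init__(self) -> None:
        for label, (x, n) in (("control", self.control), ("mutant", self.mutant)):
            if not (0 <= x <= n):
                raise ValueError(f"{label} cell ({x}/{n}) violates 0 <= abnormal <= total")


# ---------------------------------------------------------------------------
# Bias-reduced (Firth) logistic regression


def _penalized_loglik(beta: np.ndarray, X: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    eta = X @ beta
    # log-lik written via logaddexp for numerical safety at extreme eta
    ll = float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))
    p = 1.0 / (1.0 + np.exp(-eta))
    W = w * p * (1.0 - p)
    info = (X * W[:, None]).T @ X
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def firth_logistic_fit(
    y: Sequence[int] | np.ndarray,
    X: np.ndarray,
    names: Sequence[str] | None = None,
    sample_weight: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
    n_constrained: int = 0,
) -> FitResult:
    """Fit logistic regression by maximizing the Jeffreys-penalized likelihood.

    The penalty 1/2 log det I(beta) removes the leading-order small-sample
    bias of the MLE and yields finite estimates even under complete
    separation. ``sample_weight`` takes frequency weights so 2x2 tables can
    be fitted from their counts. With ``n_constrained`` > 0 the last that
    many coefficients are held at zero while the penalty keeps the full
    design's information — the constrained fit a penalized LR test needs.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    w = np.ones_like(y) if sample_weight is None else np.asarray(sample_weight, dtype=float)
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("design matrix is rank deficient")
    names = list(names) if names is not None else [f"x{j}" for j in range(k)]
    free = np.arange(k) < (k - n_constrained)

    beta = np.zeros(k)
    ll = _penalized_loglik(beta, X, y, w)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        W = w * p * (1.0 - p)
        XW = X * W[:, None]
        info = XW.T @ X
        info_inv = np.linalg.inv(info)
        # hat-matrix diagonal of the weighted (full) design
        h = np.einsum("ij,jk,ik->i", XW, info_inv, X)
        score = X[:, free].T @ (w * (y - p) + h * (0.5 - p))
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        step_free = np.linalg.solve(info[np.ix_(free, free)], score)
        step = np.zeros(k)
        step[free] = step_free
        # step-halving keeps the penalized likelihood monotone
        for _ in range(30):
            new_ll = _penalized_loglik(beta + step, X, y, w)
            if new_ll >= ll - 1e-12:
                break
            step *= 0.5
        beta = beta + step
        ll = new_ll
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    W = w * p * (1.0 - p)
    cov = np.linalg.inv((X * W[:, None]).T @ X)
    se = np.sqrt(np.diag(cov))
    return FitResult(
        estimates=dict(zip(names, beta)),
        standard_errors=dict(zip(names, se)),
        log_likelihood=_penalized_loglik(beta, X, y, w),
        converged=converged,
        n_obs=int(round(w.sum())),
        method="br_logistic",
        n_fixed=int(free.sum()),
        fingerprint=(n, float(np.sum(w * y)), float(w.sum())),
        flags=[] if converged else ["max_iter_reached"],
    )


def _spans(null_X: np.ndarray, full_X: np.ndarray) -> bool:
    """True iff the column space of null_X lies inside that of full_X."""
    full_X = np.atleast_2d(full_X)
    null_X = np.atleast_2d(null_X)
    aug = np.hstack([full_X, null_X])
    return np.linalg.matrix_rank(aug) == np.linalg.matrix_rank(full_X)


def firth_lr_test(
    y: Sequence[int] | np.ndarray,
    full_design: np.ndarray,
    null_design: np.ndarray,
    sample_weight: np.ndarray | None = None,
) -> TestOutcome:
    """Penalized-likelihood-ratio test between nested logistic models.

    Both likelihoods carry the full design's Jeffreys penalty: the null is
    the full model with the extra coefficients constrained to zero (the
    profile construction of the bias-reduction literature), so the
    statistic is non-negative and vanishes when the data carry no signal
    for the tested terms. Referred to a chi-square with df equal to the
    rank difference.
    """
    full_design = np.atleast_2d(np.asarray(full_design, dtype=float))
    null_design = np.atleast_2d(np.asarray(null_design, dtype=float))
    if not _spans(null_design, full_design):
        raise ValueError("null design is not nested within the full design")
    rank_null = np.linalg.matrix_rank(null_design)
    df = np.linalg.matrix_rank(full_design) - rank_null
    if df == 0:
        return TestOutcome(0.0, 0, 1.0, "two_sided", "br_logistic_lr")
    # reparametrize as [null | complement]: pick full columns that extend
    # the null column space so the constrained fit is well defined
    A = null_design
    for j in range(full_design.shape[1]):
        cand = np.hstack([A, full_design[:, j : j + 1]])
        if np.linalg.matrix_rank(cand) > np.linalg.matrix_rank(A):
            A = cand
    full = firth_logistic_fit(y, A, sample_weight=sample_weight)
    null = firth_logistic_fit(
        y, A, sample_weight=sample_weight, n_constrained=A.shape[1] - rank_null
    )
    stat = max(0.0, 2.0 * (full.log_likelihood - null.log_likelihood))
    p = float(sps.chi2.sf(stat, df))
    return TestOutcome(stat, df, p, "two_sided", "br_logistic_lr")


# ---------------------------------------------------------------------------
# Exact stratified CMH mid-p and attainability filters


def cmh_null_distribution(
    margins: Sequence[tuple[int, int, int]],
) -> tuple[np.ndarray, np.ndarray]:
    """Exact conditional null of the total mutant abnormal count.

    ``margins``: per stratum (n_control, n_mutant, n_abnormal_total). With
    all margins fixed, the per-stratum mutant abnormal count is
    hypergeometric and the total is their convolution. Returns
    (support, pmf).
    """
    support = np.array([0])
    pmf = np.array([1.0])
    for n_control, n_mutant, n_abn in margins:
        n_total = n_control + n_mutant
        if not (0 <= n_abn <= n_total):
            raise ValueError("abnormal margin exceeds stratum size")
        lo = max(0, n_abn - n_control)
        hi = min(n_abn, n_mutant)
        ts = np.arange(lo, hi + 1)
        ps = sps.hypergeom.pmf(ts, n_total, n_abn, n_mutant)
        pmf = np.convolve(pmf, ps)
        support = np.arange(support[0] + lo, support[0] + lo + len(pmf))
    pmf = pmf / pmf.sum()
    return support, pmf


def _strata_margins(strata: Iterable[StratumTable]) -> list[tuple[int, int, int]]:
    return [(s.control[1], s.mutant[1], s.control[0] + s.mutant[0]) for s in strata]


def cmh_midp_onesided(
    strata: Sequence[StratumTable],
    direction: str = "mutant_higher",
) -> TestOutcome:
    """Exact one-sided Cochran–Mantel–Haenszel mid-p test.

    Conditions on all margins; the test statistic is the total mutant
    abnormal count across strata. The mid-p counts only half the
    probability of the observed total, reducing the conservatism of the
    discrete null. Degenerate tables (single-point null) give p = 1 by
    convention.
    """
    if not strata:
        raise ValueError("at least one stratum required")
    margins = _strata_margins(strata)
    support, pmf = cmh_null_distribution(margins)
    if len(support) == 1:
        return TestOutcome(float(support[0]), 0, 1.0, "one_sided", "cmh_midp")
    t_obs = sum(s.mutant[0] for s in strata)
    idx = int(t_obs - support[0])
    if direction == "mutant_higher":
        p = float(pmf[idx + 1:].sum() + 0.5 * pmf[idx])
    elif direction == "mutant_lower":
        p = float(pmf[:idx].sum() + 0.5 * pmf[idx])
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return TestOutcome(float(t_obs), 0, min(p, 1.0), "one_sided", "cmh_midp")


def mh_alpha_star(
    margins: Sequence[tuple[int, int, int]],
    direction: str = "mutant_higher",
) -> float:
    """Minimal attainable CMH mid-p for fixed margins.

    Used at threshold 0.05 to skip data sets that could never reach
    significance, which lowers the multiplicity burden. A degenerate null
    (for example zero abnormal anywhere) returns 1.
    """
    support, pmf = cmh_null_distribution(margins)
    if len(support) == 1:
        return 1.0
    if direction == "mutant_higher":
        return float(0.5 * pmf[-1])
    if direction == "mutant_lower":
        return float(0.5 * pmf[0])
    raise ValueError(f"unknown direction {direction!r}")


@functools.lru_cache(maxsize=100_000)
def _firth_sex_lr_2x2(f_abn: int, f_n: int, m_abn: int, m_n: int) -> float:
    """Penalized LR p for sex on a 2x2 abnormality table, via counts."""
    X_full = np.array([[1.0, 0.0], [1.0, 1.0]])  # rows: female, male
    X_null = X_full[:, :1]
    y = np.array([1.0, 1.0, 0.0, 0.0])
    Xf = np.vstack([X_full, X_full])
    Xn = np.vstack([X_null, X_null])
    w = np.array([f_abn, m_abn, f_n - f_abn, m_n - m_abn], dtype=float)
    keep = w > 0
    if not keep.any():
        return 1.0
    return firth_lr_test(y[keep], Xf[keep], Xn[keep], sample_weight=w[keep]).p_value


def lrko_alpha_star(n_abnormal: int, n_female: int, n_male: int) -> float:
    """Minimal attainable penalized-LR p over allocations of abnormal calls.

    For the stage-2 knockout-only sex test, the most extreme p arises from
    some split of the observed abnormal count between the sexes; the filter
    passes a data set only when that minimum is below threshold.
    """
    if not (0 <= n_abnormal <= n_female + n_male):
        raise ValueError("abnormal count exceeds readings")
    lo = max(0, n_abnormal - n_male)
    hi = min(n_abnormal, n_female)
    return min(
        _firth_sex_lr_2x2(f_abn, n_female, n_abnormal - f_abn, n_male)
        for f_abn in range(lo, hi + 1)
    )


# ---------------------------------------------------------------------------
# Multiplicity, intervals, standardization, overlap


def multiplicity_adjust(
    p_values: Sequence[float] | np.ndarray,
    method: str = "hochberg_stepup",
    level: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Step-up multiple-testing adjustment.

    ``hochberg_stepup`` is Hochberg's step-up procedure (the method the
    pipelines name); ``benjamini_hochberg`` is the BH FDR step-up. Returns
    (adjusted p-values, significance flags at ``level``).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    sm_method = {"hochberg_stepup": "simes-hochberg", "benjamini_hochberg": "fdr_bh"}[method]
    _, adj, _, _ = multipletests(p, alpha=level, method=sm_method)
    return adj, adj <= level


def newcombe_diff_ci(x1: int, n1: int, x2: int, n2: int, level: float = 0.95) -> Interval:
    """Newcombe hybrid score interval for a difference of two proportions.

    Combines per-group Wilson score limits by the square-and-add rule
    (Newcombe method 10): non-degenerate even at 0/n or n/n.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    alpha = 1.0 - level
    p1, p2 = x1 / n1, x2 / n2
    l1, u1 = proportion_confint(x1, n1, alpha=alpha, method="wilson")
    l2, u2 = proportion_confint(x2, n2, alpha=alpha, method="wilson")
    diff = p1 - p2
    lower = diff - np.sqrt((p1 - l1) ** 2 + (u2 - p2) ** 2)
    upper = diff + np.sqrt((u1 - p1) ** 2 + (p2 - l2) ** 2)
    return Interval(point=diff, lower=float(max(lower, -1.0)), upper=float(min(upper, 1.0)), level=level)


def standardize_effect(
    estimate: float,
    se: float,
    wt_mean_female: float,
    wt_mean_male: float,
    tol: float = 1e-8,
) -> tuple[float, float]:
    """Scale an effect by the average of the wildtype sex means.

    Puts genotype effects for traits with different units on one scale; the
    denominator is (mean_female + mean_male)/2 of the wildtype signal.
    Refused (ValueError) when the denominator is within ``tol`` of zero.
    """
    denom = 0.5 * (wt_mean_female + wt_mean_male)
    if abs(denom) < tol:
        raise ValueError("wildtype signal too close to zero to standardize against")
    return estimate / denom, se / denom


def jaccard_similarity(set_a: Iterable[str], set_b: Iterable[str]) -> float:
    """|A∩B| / |A∪B| on case-normalized identifier sets (0 if both empty)."""
    a = {str(x).casefold() for x in set_a}
    b = {str(x).casefold() for x in set_b}
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)
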