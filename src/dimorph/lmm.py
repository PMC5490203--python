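"""Linear mixed models with batch random intercepts.

The phenotyping analyses model each continuous trait as fixed effects
(sex, genotype, body weight and their interactions) plus a random
intercept shared by all animals measured in the same batch (calendar date
at one centre), plus residual noise whose variance is either homogeneous
or stratified by a declared grouping factor (sex for wildtype analyses,
genotype for mutant analyses). The residual structure is chosen by AIC on
maximum-likelihood fits, and nested fixed-effect structures are compared
by likelihood-ratio tests (ML, not REML, because the fixed parts differ).

statsmodels' MixedLM cannot stratify the residual variance, so the
marginal Gaussian likelihood is implemented directly: the covariance of a
batch block is D + sigma_b^2 * 11' with D diagonal, inverted analytically
via Sherman–Morrison, and the fixed effects are profiled out by GLS at
each variance evaluation.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .stats import FitResult, TestOutcome

__all__ = ["mixed_model_fit", "mixed_lr_test", "mixed_lr"]


def _profile_nll(
    log_params: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    batch_idx: np.ndarray,
    n_batches: int,
    group_idx: np.ndarray,
    n_groups: int,
    include_batch: bool,
    want_beta: bool = False,
):
    """Negative ML log-likelihood with fixed effects profiled out by GLS."""
    if include_batch:
        s2b = np.exp(log_params[0])
        s2g = np.exp(log_params[1:])
    else:
        s2b = 0.0
        s2g = np.exp(log_params)
    d = s2g[group_idx]  # per-row residual variance
    inv_d = 1.0 / d
    n, k = X.shape

    Xd = X * inv_d[:, None]
    M = Xd.T @ X                      # X' D^-1 X
    v = Xd.T @ y                      # X' D^-1 y
    q = float(np.sum(y * y * inv_d))  # y' D^-1 y
    logdet = float(np.sum(np.log(d)))

    if include_batch and s2b > 0.0:
        S1 = np.bincount(batch_idx, weights=inv_d, minlength=n_batches)
        Sy = np.bincount(batch_idx, weights=y * inv_d, minlength=n_batches)
        SX = np.empty((n_batches, k))
        for j in range(k):
            SX[:, j] = np.bincount(batch_idx, weights=Xd[:, j], minlength=n_batches)
        c = s2b / (1.0 + s2b * S1)
        M -= (SX * c[:, None]).T @ SX
        v -= SX.T @ (c * Sy)
        q -= float(np.sum(c * Sy * Sy))
        logdet += float(np.sum(np.log1p(s2b * S1)))

    try:
        beta = np.linalg.solve(M, v)
    except np.linalg.LinAlgError:
        return (np.inf, None, None) if want_beta else np.inf
    quad = q - float(beta @ v)  # (y - X beta)' V^-1 (y - X beta)
    nll = 0.5 * (n * np.log(2.0 * np.pi) + logdet + quad)
    if want_beta:
        return nll, beta, M
    return nll


def _fit_structure(
    y: np.ndarray,
    X: np.ndarray,
    batch_idx: np.ndarray,
    n_batches: int,
    group_idx: np.ndarray,
    n_groups: int,
    include_batch: bool,
) -> dict:
    var_y = max(float(np.var(y)), 1e-12)
    lo, hi = np.log(var_y) - 25.0, np.log(var_y) + 6.0
    x0 = []
    if include_batch:
        x0.append(np.log(0.1 * var_y))
    x0.extend([np.log(var_y)] * n_groups)
    args = (y, X, batch_idx, n_batches, group_idx, n_groups, include_batch)
    res = optimize.minimize(
        _profile_nll,
        np.array(x0),
        args=args,
        method="L-BFGS-B",
        bounds=[(lo, hi)] * len(x0),
        options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-8},
    )
    if not res.success:
        # L-BFGS line searches can fail near variance boundaries although
        # the optimum is fine; polish derivative-free before giving up
        polish = optimize.minimize(
            _profile_nll, res.x, args=args, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
        )
        if polish.fun <= res.fun + 1e-12:
            res = polish
    nll, beta, M = _profile_nll(
        res.x, y, X, batch_idx, n_batches, group_idx, n_groups, include_batch, want_beta=True
    )
    cov = np.linalg.inv(M)
    theta = np.exp(res.x)
    return {
        "ll": -nll,
        "beta": beta,
        "cov": cov,
        "batch_var": float(theta[0]) if include_batch else 0.0,
        "resid_vars": theta[1:] if include_batch else theta,
        "converged": bool(res.success),
        "n_varparams": len(x0),
    }


def mixed_model_fit(
    data: pd.DataFrame,
    response: str,
    fixed: Sequence[str],
    batch: str = "batch_label",
    residual_group: str | None = None,
    candidates: Sequence[str] = ("homogeneous", "stratified"),
    selection: str = "lrt",
    selection_alpha: float = 0.01,
) -> FitResult:
    """ML fit of ``response ~ 1 + fixed + (1 | batch)`` with residual-structure
    selection.

    ``fixed`` names numeric columns of ``data`` (build dummies/interactions
    beforehand). Candidate residual structures are a single variance
    ("homogeneous") and one variance per level of ``residual_group``
    ("stratified"). With ``selection="lrt"`` (default) the stratified
    structure is kept only when it improves the likelihood significantly
    (chi-square LR test at ``selection_alpha``); ``selection="aic"`` keeps
    the AIC-best candidate. The LR rule is the default because greedy AIC
    selection adopts the extra variance parameter often enough under the
    null to inflate downstream fixed-effect tests. A data set whose
    observations all share one batch is fitted without the random term and
    flagged.
    """
    cols = [response, *fixed, batch] + ([residual_group] if residual_group else [])
    d = data.dropna(subset=[c for c in dict.fromkeys(cols)])
    y = d[response].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(d))] + [d[c].to_numpy(dtype=float) for c in fixed])
    names = ["intercept", *fixed]
    if len(d) <= X.shape[1]:
        raise ValueError("fewer observations than fixed-effect parameters")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design is rank deficient")

    batch_codes, batch_levels = pd.factorize(d[batch])
    include_batch = len(batch_levels) > 1
    flags = [] if include_batch else ["single_batch_random_term_dropped"]

    structures: dict[str, dict] = {}
    if "homogeneous" in candidates:
        structures["homogeneous"] = (np.zeros(len(d), dtype=int), 1, None)
    if "stratified" in candidates and residual_group is not None:
        g_codes, g_levels = pd.factorize(d[residual_group])
        if len(g_levels) > 1:
            structures["stratified"] = (g_codes, len(g_levels), list(map(str, g_levels)))
    if not structures:
        raise ValueError("no admissible residual structure candidate")

    fits = {}
    for label, (g_idx, n_g, g_names) in structures.items():
        fit = _fit_structure(y, X, batch_codes, len(batch_levels), g_idx, n_g, include_batch)
        fit["aic"] = 2.0 * (X.shape[1] + fit["n_varparams"]) - 2.0 * fit["ll"]
        fit["group_names"] = g_names
        fits[label] = fit
    if len(fits) == 1:
        best_label = next(iter(fits))
    elif selection == "aic":
        best_label = min(fits, key=lambda s: fits[s]["aic"])
    elif selection == "lrt":
        stat = max(0.0, 2.0 * (fits["stratified"]["ll"] - fits["homogeneous"]["ll"]))
        df_sel = fits["stratified"]["n_varparams"] - fits["homogeneous"]["n_varparams"]
        keep = sps.chi2.sf(stat, df_sel) < selection_alpha
        best_label = "stratified" if keep else "homogeneous"
    else:
        raise ValueError(f"unknown selection rule {selection!r}")
    best = fits[best_label]

    vc = {"batch": best["batch_var"]}
    if best_label == "homogeneous":
        vc["residual"] = float(best["resid_vars"][0])
    else:
        for gname, v in zip(best["group_names"], best["resid_vars"]):
            vc[f"residual[{gname}]"] = float(v)
    se = np.sqrt(np.diag(best["cov"]))
    return FitResult(
        estimates=dict(zip(names, best["beta"])),
        standard_errors=dict(zip(names, se)),
        log_likelihood=float(best["ll"]),
        converged=best["converged"],
        n_obs=len(d),
        method="mixed_ml",
        residual_structure=best_label,
        variance_components=vc,
        aic=float(best["aic"]),
        n_fixed=X.shape[1],
        fingerprint=(len(d), float(y.sum()), float(np.sum(y * y))),
        flags=flags,
    )


def mixed_lr_test(full: FitResult, null: FitResult) -> TestOutcome:
    """Chi-square LR test between nested ML mixed fits on the same data."""
    if full.fingerprint != null.fingerprint:
        raise ValueError("full and null fits were not computed on the same data")
    if full.residual_structure != null.residual_structure:
        raise ValueError("full and null fits must share the residual structure")
    df = full.n_fixed - null.n_fixed
    if df <= 0:
        return TestOutcome(0.0, 0, 1.0, "two_sided", "mixed_lr")
    stat = max(0.0, 2.0 * (full.log_likelihood - null.log_likelihood))
    return TestOutcome(stat, df, float(sps.chi2.sf(stat, df)), "two_sided", "mixed_lr")


def mixed_lr(
    data: pd.DataFrame,
    response: str,
    full_terms: Sequence[str],
    null_terms: Sequence[str],
    batch: str = "batch_label",
    residual_group: str | None = None,
) -> tuple[TestOutcome, FitResult, FitResult]:
    """Fit full model with structure selection, refit null under the selected
    structure, and LR-test the nested fixed terms."""
    full = mixed_model_fit(data, response, full_terms, batch, residual_group)
    null = mixed_model_fit(
        data, response, null_terms, batch, residual_group, candidates=(full.residual_structure,)
    )
    return mixed_lr_test(full, null), full, null
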