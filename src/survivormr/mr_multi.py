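"""Multivariable two-sample MR with weak-instrument and pleiotropy diagnostics.

Estimation regresses variant-outcome effects on the matrix of variant-exposure
effects without an intercept, weighted by the inverse outcome-side variance.
Diagnostics:

* the multivariable Q-statistic — weighted residual heterogeneity whose
  weights propagate exposure-side uncertainty under a zero-covariance
  assumption (non-overlapping exposure samples); inflation signals genetic
  pleiotropy *or* selection bias, which is exactly why this package reports it;
* the conditional F-statistic per exposure — instrument strength for one
  exposure given the others, a lower bound under zero covariance;
* the multivariable MR-Egger intercept — directional pleiotropy, fitted with
  an intercept after orienting every variant to a non-negative effect on a
  chosen exposure.

Degrees of freedom follow the usual conventions: ``k - K`` for Q and the IVW
overdispersion, ``k - K - 1`` for Egger.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2, norm

from .sumstats import HarmonizedDataset

__all__ = [
    "MVMREstimate",
    "mvmr_ivw",
    "mvmr_q",
    "conditional_f",
    "mvmr_egger",
    "mvmr",
]

Z95 = 1.959963984540054


@dataclass
class MVMREstimate:
    """Adjusted causal effects for K exposures plus the diagnostic battery."""

    theta: np.ndarray
    se_theta: np.ndarray
    or_: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    q_a: float
    q_pval: float
    cond_f: np.ndarray
    egger_intercept: float
    egger_intercept_se: float
    egger_intercept_pval: float
    egger_theta: np.ndarray
    k: int
    K: int
    exposure_ids: list[str] = field(default_factory=list)
    notes: str = (
        "zero covariance assumed between exposure-effect estimates; "
        "conditional F is a lower bound on instrument strength and Q an "
        "upper bound on pleiotropy/selection heterogeneity"
    )

    def __post_init__(self) -> None:
        if self.q_a < 0:
            raise ValueError("q_a must be >= 0")
        if np.any(self.cond_f < 0):
            raise ValueError("conditional F entries must be >= 0")
        if not self.k > self.K:
            raise ValueError("more variants than exposures required (k > K)")


def _check_rank(bx: np.ndarray, exposure_ids: list[str]) -> None:
    rank = np.linalg.matrix_rank(bx)
    if rank < bx.shape[1]:
        corr = np.corrcoef(bx, rowvar=False)
        pairs = [
            f"{exposure_ids[i]}~{exposure_ids[j]}"
            for i in range(len(exposure_ids))
            for j in range(i + 1, len(exposure_ids))
            if abs(corr[i, j]) > 0.999
        ]
        detail = f" (collinear: {', '.join(pairs)})" if pairs else ""
        raise np.linalg.LinAlgError(
            f"exposure-effect matrix is rank deficient{detail}"
        )


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Weighted least squares via normal equations; returns (coef, cov_unscaled, wrss)."""
    Xw = X * w[:, None]
    xtx = X.T @ Xw
    coef = np.linalg.solve(xtx, Xw.T @ y)
    resid = y - X @ coef
    wrss = float(np.sum(w * resid**2))
    cov = np.linalg.inv(xtx)
    return coef, cov, wrss


def mvmr_ivw(h: HarmonizedDataset) -> tuple[np.ndarray, np.ndarray, float]:
    """Weighted no-intercept regression of by on bx, weights ``1/se_by^2``.

    Returns ``(theta, se_theta, wrss)``.  The standard errors come from the
    inverse weighted normal-equations matrix scaled by the multiplicative
    overdispersion factor ``max(1, sqrt(wrss / (k - K)))``, so that with a
    single exposure the estimate and SE coincide exactly with the
    regression form of univariable IVW.
    """
    k, K = h.k, h.K
    if k <= K:
        raise ValueError(f"need more variants than exposures (k={k}, K={K})")
    _check_rank(h.bx, h.exposure_ids)
    w = 1.0 / h.se_by**2
    theta, cov, wrss = _wls(h.bx, h.by, w)
    df = k - K
    dispersion = max(1.0, math.sqrt(wrss / df))
    se_theta = dispersion * np.sqrt(np.diag(cov))
    return theta, se_theta, wrss


def mvmr_q(
    h: HarmonizedDataset,
    theta: np.ndarray,
    iterate: bool = False,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[float, float]:
    """Multivariable Q-statistic with exposure-uncertainty-propagating weights.

    ``q_a = sum_i (by_i - bx_i . theta)^2 / (se_by_i^2 + sum_j theta_j^2 se_bx_ij^2)``
    against chi-square with ``k - K`` degrees of freedom.  With
    ``iterate=True`` theta is re-estimated under the q_a weights until the
    change falls below ``tol`` (plug-in theta is the default; the two choices
    agree closely when instruments are strong).
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (h.K,):
        raise ValueError("theta must have length K")
    if h.k <= h.K:
        raise ValueError("need more variants than exposures")

    def weights(th: np.ndarray) -> np.ndarray:
        return h.se_by**2 + (h.se_bx**2) @ th**2

    if iterate:
        for _ in range(max_iter):
            w = 1.0 / weights(theta)
            new_theta, _, _ = _wls(h.bx, h.by, w)
            if np.max(np.abs(new_theta - theta)) < tol:
                theta = new_theta
                break
            theta = new_theta
    resid = h.by - h.bx @ theta
    q_a = float(np.sum(resid**2 / weights(theta)))
    q_pval = float(chi2.sf(q_a, h.k - h.K))
    return q_a, q_pval


def mvmr_q_min_theta(
    h: HarmonizedDataset, theta0: np.ndarray, tol: float = 1e-8, max_iter: int = 100
) -> np.ndarray:
    """Fixed point of the q_a weighting: theta that is the WLS solution under
    weights computed at itself (the 'minimizing theta of its own weights')."""
    theta = np.asarray(theta0, dtype=float)
    for _ in range(max_iter):
        w = 1.0 / (h.se_by**2 + (h.se_bx**2) @ theta**2)
        new_theta, _, _ = _wls(h.bx, h.by, w)
        if np.max(np.abs(new_theta - theta)) < tol:
            return new_theta
        theta = new_theta
    return theta


def conditional_f(h: HarmonizedDataset, j: int) -> float:
    """Conditional instrument strength for exposure ``j`` given the others.

    K = 1: the mean per-variant chi-square ``(bx_i / se_bx_i)^2``.  K >= 2:
    exposure j's effects are regressed (no intercept) on the other exposures'
    effects with weights ``1/se_bx_ij^2``; the weighted residual sum of
    squares, divided by ``k - K + 1``, is the heterogeneity-based conditional
    F.  Computed under zero covariance between exposure estimates, so it is a
    lower bound on the true strength.
    """
    k, K = h.k, h.K
    if not (0 <= j < K):
        raise IndexError("exposure index out of range")
    if k <= K:
        raise ValueError("need more variants than exposures")
    z2 = (h.bx[:, j] / h.se_bx[:, j]) ** 2
    if K == 1:
        return float(np.mean(z2))
    others = [c for c in range(K) if c != j]
    X = h.bx[:, others]
    w = 1.0 / h.se_bx[:, j] ** 2
    _, _, q_xj = _wls(X, h.bx[:, j], w)
    return q_xj / (k - K + 1)


def mvmr_egger(
    h: HarmonizedDataset, orient_exposure: int = 0
) -> tuple[float, float, float, np.ndarray]:
    """Multivariable MR-Egger: intercept as directional-pleiotropy probe.

    Each variant's row is sign-flipped so its effect on ``orient_exposure``
    is non-negative, then by is regressed on bx *with* an intercept, weights
    ``1/se_by^2``; the intercept SE carries the multiplicative overdispersion
    factor with ``k - K - 1`` degrees of freedom.  Returns
    ``(intercept, intercept_se, intercept_pval, slope_vector)``.
    """
    k, K = h.k, h.K
    if k <= K + 1:
        raise ValueError(f"MR-Egger requires k > K + 1 (k={k}, K={K})")
    orient = h.bx[:, orient_exposure]
    if np.all(orient == 0):
        raise ValueError("cannot orient: all effects on the orientation exposure are zero")
    flip = np.where(orient < 0, -1.0, 1.0)
    bx = h.bx * flip[:, None]
    by = h.by * flip
    _check_rank(bx, h.exposure_ids)
    X = np.column_stack([np.ones(k), bx])
    w = 1.0 / h.se_by**2
    coef, cov, wrss = _wls(X, by, w)
    df = k - K - 1
    dispersion = max(1.0, math.sqrt(wrss / df))
    se = dispersion * np.sqrt(np.diag(cov))
    intercept, intercept_se = float(coef[0]), float(se[0])
    pval = float(2.0 * norm.sf(abs(intercept / intercept_se)))
    return intercept, intercept_se, pval, coef[1:]


def mvmr(h: HarmonizedDataset, orient_exposure: int = 0,
         iterate_q: bool = False) -> MVMREstimate:
    """Full multivariable analysis: estimates plus the diagnostic battery."""
    theta, se_theta, _ = mvmr_ivw(h)
    q_a, q_pval = mvmr_q(h, theta, iterate=iterate_q)
    cf = np.array([conditional_f(h, j) for j in range(h.K)])
    if h.k > h.K + 1:
        egger_i, egger_se, egger_p, egger_theta = mvmr_egger(h, orient_exposure)
    else:  # too few variants for an intercept; report NaNs rather than fail
        egger_i = egger_se = egger_p = float("nan")
        egger_theta = np.full(h.K, np.nan)
    return MVMREstimate(
        theta=theta,
        se_theta=se_theta,
        or_=np.exp(theta),
        ci_low=np.exp(theta - Z95 * se_theta),
        ci_high=np.exp(theta + Z95 * se_theta),
        q_a=q_a,
        q_pval=q_pval,
        cond_f=cf,
        egger_intercept=egger_i,
        egger_intercept_se=egger_se,
        egger_intercept_pval=egger_p,
        egger_theta=egger_theta,
        k=h.k,
        K=h.K,
        exposure_ids=list(h.exposure_ids),
    )
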