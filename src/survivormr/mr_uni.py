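"""Univariable two-sample MR: Wald ratios and IVW meta-analysis.

The causal effect of the exposure on the outcome is estimated per variant as
the Wald ratio (variant-on-outcome over variant-on-exposure) and pooled by
inverse-variance weighting with *multiplicative* random effects: the fixed
effect standard error is scaled by ``max(1, sqrt(Q / (k - 1)))``, so
heterogeneity can widen the interval but never narrow it.  With a binary
outcome the pooled effect is a log-odds ratio per unit of exposure and is
reported as an OR with a normal-quantile 95% interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .sumstats import HarmonizedDataset

__all__ = ["WaldEstimate", "MREstimate", "wald_ratio", "ivw", "ivw_regression"]

Z95 = 1.959963984540054  # normal 97.5% quantile


@dataclass
class WaldEstimate:
    """Single-variant ratio estimate with its delta-method standard error."""

    ratio: float
    se: float
    variant_id: str = ""

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("se must be > 0")


@dataclass
class MREstimate:
    """Pooled MR estimate on the log-OR scale with OR-scale reporting."""

    beta: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    q: float
    q_pval: float
    k: int
    dispersion: float
    exposure_id: str = ""
    outcome_id: str = ""

    def __post_init__(self) -> None:
        if not (self.ci_low < self.or_ < self.ci_high):
            raise ValueError("confidence interval must bracket the OR")
        if self.q < 0 or self.dispersion < 1:
            raise ValueError("q must be >= 0 and dispersion >= 1")


def wald_ratio(bx: float, se_bx: float, by: float, se_by: float,
               variant_id: str = "", second_order: bool = False) -> WaldEstimate:
    """Variant-on-outcome effect divided by variant-on-exposure effect.

    First-order delta-method SE ``|se_by / bx|`` by default (the conventional
    choice, ignoring exposure-side uncertainty); ``second_order=True`` adds
    the ``by^2 se_bx^2 / bx^4`` term.
    """
    if bx == 0:
        raise ZeroDivisionError("Wald ratio undefined for bx = 0")
    ratio = by / bx
    if second_order:
        se = math.sqrt(se_by**2 / bx**2 + by**2 * se_bx**2 / bx**4)
    else:
        se = abs(se_by / bx)
    return WaldEstimate(ratio=ratio, se=se, variant_id=variant_id)


def _pool(ratios: np.ndarray, ses: np.ndarray, k: int) -> tuple[float, float, float, float, float]:
    w = 1.0 / ses**2
    beta = float(np.sum(w * ratios) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (ratios - beta) ** 2))
    if k >= 2:
        dispersion = max(1.0, math.sqrt(q / (k - 1)))
        q_pval = float(chi2.sf(q, k - 1))
    else:
        dispersion = 1.0
        q_pval = float("nan")
    return beta, se_fixed, q, q_pval, dispersion


def ivw(h: HarmonizedDataset, second_order: bool = False,
        outcome_id: str = "") -> MREstimate:
    """Inverse-variance-weighted pooling of Wald ratios, multiplicative random effects.

    Requires a single-exposure dataset (K = 1).  Cochran's Q is computed
    against the pooled estimate with the same first-order weights; the
    multiplicative dispersion factor ``max(1, sqrt(Q/(k-1)))`` scales the SE.
    """
    if h.K != 1:
        raise ValueError("univariable IVW requires exactly one exposure (K = 1)")
    if h.k < 1:
        raise ValueError("at least one variant required")
    if np.any(h.bx[:, 0] == 0):
        raise ZeroDivisionError("Wald ratio undefined for bx = 0")
    wald = [
        wald_ratio(h.bx[i, 0], h.se_bx[i, 0], h.by[i], h.se_by[i],
                   variant_id=h.variant_ids[i], second_order=second_order)
        for i in range(h.k)
    ]
    ratios = np.array([w.ratio for w in wald])
    ses = np.array([w.se for w in wald])
    beta, se_fixed, q, q_pval, dispersion = _pool(ratios, ses, h.k)
    se = dispersion * se_fixed
    return MREstimate(
        beta=beta, se=se, or_=math.exp(beta),
        ci_low=math.exp(beta - Z95 * se), ci_high=math.exp(beta + Z95 * se),
        q=q, q_pval=q_pval, k=h.k, dispersion=dispersion,
        exposure_id=h.exposure_ids[0], outcome_id=outcome_id,
    )


def ivw_regression(h: HarmonizedDataset, outcome_id: str = "") -> MREstimate:
    """Zero-intercept weighted regression form of univariable IVW.

    Regresses ``by`` on ``bx`` through the origin with weights ``1/se_by^2``.
    Algebraically identical to :func:`ivw` with first-order weights (the
    weight of ratio i is ``bx_i^2 / se_by_i^2``); kept as the K = 1 reduction
    check for the multivariable estimator.
    """
    if h.K != 1:
        raise ValueError("regression-form univariable IVW requires K = 1")
    bx = h.bx[:, 0]
    w = 1.0 / h.se_by**2
    sxx = float(np.sum(w * bx * bx))
    beta = float(np.sum(w * bx * h.by) / sxx)
    se_fixed = sxx**-0.5
    q = float(np.sum(w * (h.by - beta * bx) ** 2))
    if h.k >= 2:
        dispersion = max(1.0, math.sqrt(q / (h.k - 1)))
        q_pval = float(chi2.sf(q, h.k - 1))
    else:
        dispersion, q_pval = 1.0, float("nan")
    se = dispersion * se_fixed
    return MREstimate(
        beta=beta, se=se, or_=math.exp(beta),
        ci_low=math.exp(beta - Z95 * se), ci_high=math.exp(beta + Z95 * se),
        q=q, q_pval=q_pval, k=h.k, dispersion=dispersion,
        exposure_id=h.exposure_ids[0], outcome_id=outcome_id,
    )
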