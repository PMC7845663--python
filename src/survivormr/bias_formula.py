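"""Analytic odds-ratio correction for selection on survival under competing risk.

Setting: a per-variant (or per-group) odds ratio for an outcome is estimated
among people who survived to recruitment.  Two death processes remove people
beforehand: a fraction ``p_e`` of carriers of the harmful allele (death
attributable to the genetically predicted exposure) and a fraction ``p_c`` of
potential cases of the outcome (death from the competing risk).  The two
fractions are assumed independent with ``p_e + p_c < 1``, and deaths mutually
exclusive, so survival probabilities by (carrier, case) cell are::

    carrier & case       1 - p_e - p_c
    carrier & non-case   1 - p_e
    non-carrier & case   1 - p_c
    non-carrier          1

With the odds ratio expressed for the *protective* allele (the coding in
which the biased observed OR exceeds 1), the observed and true odds ratios
are related by

    OR_obs = OR_true * (1 - p_e)(1 - p_c) / (1 - p_e - p_c)

i.e. the true OR is the observed OR multiplied by the ratio of the
probability of surviving the exposure *and* the competing risk (mutually
exclusive: ``1 - p_e - p_c``) to the probability of surviving the exposure
*or* the competing risk under independence (``(1 - p_e)(1 - p_c)``).  This is
the unique simple ratio of the two candidate survival probabilities
consistent with the reference worked example (an observed 1.00 at
``p_c = 0.25`` and 1.04 at ``p_c = 0.40`` from a true 0.96 with
``p_e = 0.10``); the derivation follows directly from the 2x2 cell-survival
table above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalFractions",
    "corrected_or",
    "observed_or",
    "reversal_fraction",
    "sensitivity_grid",
    "empirical_carrier_or",
]


@dataclass(frozen=True)
class SurvivalFractions:
    """The two death-before-recruitment probabilities feeding the correction.

    ``p_e``: fraction of harmful-allele carriers ("the exposed") dead before
    recruitment because of the genetically predicted exposure.  ``p_c``:
    fraction of potential outcome cases dead before recruitment from the
    competing risk.  Must satisfy ``p_e + p_c < 1``.
    """

    p_e: float
    p_c: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_e < 1.0 and 0.0 <= self.p_c < 1.0):
            raise ValueError("p_e and p_c must lie in [0, 1)")
        if self.p_e + self.p_c >= 1.0:
            raise ValueError("p_e + p_c must be < 1")


def _fractions(f) -> SurvivalFractions:
    if isinstance(f, SurvivalFractions):
        return f
    return SurvivalFractions(*f)


def _factor(f: SurvivalFractions) -> float:
    """(1 - p_e - p_c) / ((1 - p_e)(1 - p_c)) — always in (0, 1]."""
    return (1.0 - f.p_e - f.p_c) / ((1.0 - f.p_e) * (1.0 - f.p_c))


def corrected_or(or_obs: float, f: SurvivalFractions | tuple) -> float:
    """True OR recovered from a survivor-biased observed OR.

    ``or_obs * (1 - p_e - p_c) / ((1 - p_e)(1 - p_c))``.  The derivation
    assumes an observed OR above 1 (protective-allele coding with upward
    bias); applying it to ``or_obs <= 1`` is allowed but warned about.
    """
    f = _fractions(f)
    if or_obs <= 0:
        raise ValueError("odds ratio must be > 0")
    if or_obs <= 1.0 and (f.p_e > 0 or f.p_c > 0):
        warnings.warn(
            "correction derived for an observed OR greater than 1; "
            "interpret results outside that regime with care",
            stacklevel=2,
        )
    return or_obs * _factor(f)


def observed_or(or_true: float, f: SurvivalFractions | tuple) -> float:
    """Forward biasing: the OR expected among survivors given the true OR.

    Exact inverse of :func:`corrected_or`:
    ``or_true * (1 - p_e)(1 - p_c) / (1 - p_e - p_c)``.
    """
    f = _fractions(f)
    if or_true <= 0:
        raise ValueError("odds ratio must be > 0")
    return or_true / _factor(f)


def reversal_fraction(or_true: float, p_e: float) -> float:
    """Competing-risk death fraction ``p_c`` at which the observed OR is exactly 1.

    For a protective true OR (``0 < or_true < 1``), solves
    ``observed_or(or_true, (p_e, p_c)) = 1`` in closed form:
    ``p_c = (a - (1 - p_e)) / (a - 1)`` with ``a = or_true * (1 - p_e)``.
    A harmful true OR (> 1) is handled by its reciprocal, i.e. by relabelling
    which allele's carriers the exposure deaths remove.  Raises ``ValueError``
    when no reversal exists in the feasible range ``[0, 1 - p_e)``, including
    the null effect ``or_true = 1`` (never reverses).
    """
    if not (0.0 <= p_e < 1.0):
        raise ValueError("p_e must lie in [0, 1)")
    if or_true <= 0:
        raise ValueError("odds ratio must be > 0")
    if or_true == 1.0:
        raise ValueError("a null OR never reverses")
    if or_true > 1.0:
        return reversal_fraction(1.0 / or_true, p_e)
    a = or_true * (1.0 - p_e)
    if a == 1.0:
        raise ValueError("no finite reversal fraction for these inputs")
    p_c = (a - (1.0 - p_e)) / (a - 1.0)
    if not (0.0 <= p_c < 1.0 - p_e):
        raise ValueError(
            f"reversal fraction {p_c:.4f} outside the feasible range [0, {1 - p_e:.4f})"
        )
    return p_c


def sensitivity_grid(or_obs: float, p_e_grid, p_c_grid) -> pd.DataFrame:
    """Corrected OR over a grid of survival fractions, for sensitivity analysis.

    Rows are indexed by ``p_e``, columns by ``p_c``.  Cells with
    ``p_e + p_c >= 1`` are infeasible and flagged as NaN rather than raising.
    """
    if or_obs <= 0:
        raise ValueError("odds ratio must be > 0")
    p_e_grid = np.asarray(p_e_grid, dtype=float)
    p_c_grid = np.asarray(p_c_grid, dtype=float)
    if np.any(p_e_grid < 0) or np.any(p_e_grid >= 1) or np.any(p_c_grid < 0) or np.any(p_c_grid >= 1):
        raise ValueError("grid values must lie in [0, 1)")
    pe = p_e_grid[:, None]
    pc = p_c_grid[None, :]
    feasible = pe + pc < 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = or_obs * (1.0 - pe - pc) / ((1.0 - pe) * (1.0 - pc))
    vals = np.where(feasible, vals, np.nan)
    return pd.DataFrame(vals, index=pd.Index(p_e_grid, name="p_e"),
                        columns=pd.Index(p_c_grid, name="p_c"))


def empirical_carrier_or(carrier: np.ndarray, case: np.ndarray) -> tuple[float, float]:
    """Protective-coded odds ratio from a 2x2 carrier-by-case table.

    Returns ``(or, se_log_or)`` where the OR is the odds of being a case for
    *non-carriers* relative to carriers — the coding in which the analytic
    correction is written.  The SE is the usual ``sqrt(sum of 1/cell)``.
    """
    carrier = np.asarray(carrier, dtype=bool)
    case = np.asarray(case, dtype=bool)
    a = float(np.sum(~carrier & case))       # protective group, case
    b = float(np.sum(~carrier & ~case))
    c = float(np.sum(carrier & case))
    d = float(np.sum(carrier & ~case))
    if min(a, b, c, d) == 0:
        raise ValueError("empty cell in 2x2 table; odds ratio undefined")
    or_ = (a / b) / (c / d)
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    return or_, se
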