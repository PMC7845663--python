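"""Structural simulation of survivor-selected Mendelian-randomization studies.

The generative model is a directed acyclic graph over individual-level data:

* ``Z`` — independent biallelic variants (linkage equilibrium), dose-coded 0/1/2,
  instrumenting a continuous primary exposure ``X``;
* ``U1`` — a classic confounder of exposure and outcome;
* ``U2`` — a latent shared-etiology factor loading on heritable *shared-cause
  traits* (blood-pressure/smoking/BMI analogues), each with its own independent
  instruments and its own effects on the competing disease, on death before
  recruitment, and on the outcome;
* ``Y2`` — a binary competing disease caused by the exposure and the shared causes;
* ``S`` — survival to recruitment, Bernoulli on the log-odds-of-surviving
  scale with contributions from the exposure (or, optionally, directly from
  the instruments), the competing disease, and the shared-cause traits;
* ``Y`` — the binary outcome of interest.

Association scans downstream are run on survivors (``S = 1``) only.  Survival is
a collider between the instrumented exposure and the shared causes of the
outcome, so conditioning on it opens a backdoor path from instrument to outcome
and violates the exclusion restriction — the bias this package studies.

Two selection mechanisms are provided: the structural one above
(:func:`simulate_cohort` + :func:`select_survivors`) and the literal
tabular mechanism (:func:`apply_tabular_selection`) in which a fraction ``p_e``
of harmful-allele carriers and a fraction ``p_c`` of potential cases die before
recruitment, mutually exclusively — the mechanism the analytic odds-ratio
correction in :mod:`survivormr.bias_formula` assumes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import yaml
from scipy.special import expit

__all__ = [
    "AdjustmentTraitConfig",
    "SimulationConfig",
    "Cohort",
    "simulate_cohort",
    "select_survivors",
    "apply_tabular_selection",
    "simulate_carrier_outcome_cohort",
    "write_cohort_tsv",
    "config_to_yaml",
    "config_from_yaml",
]


def _as_vector(value, length: int, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full(length, float(arr))
    if arr.shape != (length,):
        raise ValueError(f"{name} must have length {length}, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class AdjustmentTraitConfig:
    """A heritable shared cause of survival and outcome, with its own instruments.

    The trait loads on the latent shared-etiology factor ``U2`` (coefficient
    ``beta_u2``), so several such traits are mutually correlated, as blood
    pressure, smoking and BMI are in practice.  Unlike a pure proxy it has its
    own causal effects (``beta_y2`` on the competing disease, ``beta_s`` on
    the log-odds of surviving, ``beta_y`` on the outcome), which is what makes
    multivariable adjustment for it capable of blocking the selection-induced
    backdoor path.
    """

    name: str
    maf: Sequence[float]
    beta_za: Sequence[float]
    beta_u2: float = 0.0
    beta_y2: float = 0.0
    beta_s: float = 0.0
    beta_y: float = 0.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        self.maf = np.asarray(self.maf, dtype=float)
        if self.maf.ndim != 1 or self.maf.size == 0:
            raise ValueError("maf must be a non-empty 1-d vector")
        if np.any(self.maf <= 0.0) or np.any(self.maf > 0.5):
            raise ValueError("minor-allele frequencies must lie in (0, 0.5]")
        self.beta_za = _as_vector(self.beta_za, self.maf.size, f"{self.name}.beta_za")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for coef in (self.beta_u2, self.beta_y2, self.beta_s, self.beta_y):
            if not np.isfinite(coef):
                raise ValueError("non-finite coefficient in adjustment trait")

    @property
    def n_variants(self) -> int:
        return int(self.maf.size)


@dataclass
class SimulationConfig:
    """Parameters of the structural causal model.

    All binary traits use a logistic link.  ``intercept_y2``/``beta_*y2`` and
    ``intercept_y``/``beta_*y`` are on the log-odds scale of the competing
    disease and the outcome; ``intercept_s``/``beta_xs``/``beta_zs``/
    ``beta_y2s`` are on the log-odds of *surviving* to recruitment (a large
    positive ``intercept_s`` means essentially nobody dies).  ``beta_xs``
    puts survival pressure on the instrumented exposure; ``beta_zs`` (a
    per-variant vector) puts it directly on the instruments instead — the two
    survival wirings are one field apart.  ``pleiotropy_zy`` adds direct
    variant-on-outcome effects.
    """

    n_individuals: int
    n_variants: int
    maf: Sequence[float]
    beta_zx: Sequence[float]
    sd_u1: float = 1.0
    sd_u2: float = 1.0
    beta_u1x: float = 0.0
    intercept_y2: float = -1.0
    beta_xy2: float = 0.0
    beta_u2y2: float = 0.0
    intercept_s: float = 20.0
    beta_xs: float = 0.0
    beta_zs: Sequence[float] | None = None
    beta_y2s: float = 0.0
    intercept_y: float = -2.0
    beta_xy: float = 0.0
    beta_u1y: float = 0.0
    beta_u2y: float = 0.0
    pleiotropy_zy: Sequence[float] | None = None
    noise_sd_x: float = 1.0
    seed: int = 0
    adjustment_traits: Sequence[AdjustmentTraitConfig] = field(default_factory=tuple)
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        m = self.n_variants
        self.maf = _as_vector(self.maf, m, "maf")
        if np.any(self.maf <= 0.0) or np.any(self.maf > 0.5):
            raise ValueError("minor-allele frequencies must lie in (0, 0.5]")
        self.beta_zx = _as_vector(self.beta_zx, m, "beta_zx")
        self.beta_zs = _as_vector(
            np.zeros(m) if self.beta_zs is None else self.beta_zs, m, "beta_zs"
        )
        self.pleiotropy_zy = _as_vector(
            np.zeros(m) if self.pleiotropy_zy is None else self.pleiotropy_zy,
            m,
            "pleiotropy_zy",
        )
        for name in ("sd_u1", "sd_u2", "noise_sd_x"):
            val = getattr(self, name)
            if not np.isfinite(val) or val < 0:
                raise ValueError(f"{name} must be a finite non-negative number")
        scalars = (
            self.beta_u1x, self.intercept_y2, self.beta_xy2, self.beta_u2y2,
            self.intercept_s, self.beta_xs, self.beta_y2s, self.intercept_y,
            self.beta_xy, self.beta_u1y, self.beta_u2y,
        )
        if not np.all(np.isfinite(scalars)):
            raise ValueError("non-finite coefficient in SimulationConfig")
        self.adjustment_traits = tuple(self.adjustment_traits)

    @property
    def total_variants(self) -> int:
        return self.n_variants + sum(t.n_variants for t in self.adjustment_traits)


@dataclass
class Cohort:
    """Individual-level realization of the structural model.

    ``genotypes`` holds effect-allele doses in {0, 1, 2}, one column per
    variant (primary-exposure instruments first, then each shared-cause
    trait's instruments in config order).  ``s == 1`` means survived to
    recruitment.  ``traits`` maps shared-cause trait names to their values.
    """

    genotypes: np.ndarray
    variant_ids: list[str]
    effect_alleles: list[str]
    other_alleles: list[str]
    instrument_of: list[str]
    u1: np.ndarray
    u2: np.ndarray
    x: np.ndarray
    y2: np.ndarray
    s: np.ndarray
    y: np.ndarray
    traits: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.genotypes.shape[0]
        for name in ("u1", "u2", "x", "y2", "s", "y"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"cohort array {name!r} has wrong length")
        for name, vals in self.traits.items():
            if vals.shape != (n,):
                raise ValueError(f"trait array {name!r} has wrong length")
        m = self.genotypes.shape[1]
        for name in ("variant_ids", "effect_alleles", "other_alleles", "instrument_of"):
            if len(getattr(self, name)) != m:
                raise ValueError(f"variant metadata {name!r} has wrong length")

    @property
    def n(self) -> int:
        return int(self.genotypes.shape[0])

    @property
    def n_variants(self) -> int:
        return int(self.genotypes.shape[1])

    def take(self, index: np.ndarray) -> "Cohort":
        """Row subset preserving order; variant metadata shared."""
        return Cohort(
            genotypes=self.genotypes[index],
            variant_ids=self.variant_ids,
            effect_alleles=self.effect_alleles,
            other_alleles=self.other_alleles,
            instrument_of=self.instrument_of,
            u1=self.u1[index],
            u2=self.u2[index],
            x=self.x[index],
            y2=self.y2[index],
            s=self.s[index],
            y=self.y[index],
            traits={k: v[index] for k, v in self.traits.items()},
        )


def _bernoulli(rng: np.random.Generator, logit: np.ndarray) -> np.ndarray:
    return (rng.random(logit.shape[0]) < expit(logit)).astype(np.int8)


def simulate_cohort(config: SimulationConfig, rng: np.random.Generator | None = None) -> Cohort:
    """Draw one cohort from the structural model.

    The draw order is fixed (genotypes, confounders, exposure noise, trait
    noises, competing disease, death, outcome), so a given ``(config, seed)``
    pair yields a bit-identical cohort.  Pass ``rng`` to override the config
    seed, e.g. for reproducible replicate streams.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    m = config.n_variants

    mafs = np.concatenate(
        [config.maf] + [t.maf for t in config.adjustment_traits]
    )
    genotypes = rng.binomial(2, mafs[None, :], size=(n, mafs.size)).astype(np.int8)

    u1 = rng.normal(0.0, config.sd_u1, n)
    u2 = rng.normal(0.0, config.sd_u2, n)

    gx = genotypes[:, :m].astype(float)
    x = gx @ config.beta_zx + config.beta_u1x * u1 + rng.normal(0.0, config.noise_sd_x, n)

    traits: dict[str, np.ndarray] = {}
    col = m
    for t in config.adjustment_traits:
        ga = genotypes[:, col : col + t.n_variants].astype(float)
        traits[t.name] = ga @ t.beta_za + t.beta_u2 * u2 + rng.normal(0.0, t.noise_sd, n)
        col += t.n_variants

    lp_y2 = config.intercept_y2 + config.beta_xy2 * x + config.beta_u2y2 * u2
    for t in config.adjustment_traits:
        lp_y2 = lp_y2 + t.beta_y2 * traits[t.name]
    y2 = _bernoulli(rng, lp_y2)

    lp_survive = (
        config.intercept_s
        + config.beta_xs * x
        + gx @ config.beta_zs
        + config.beta_y2s * y2
    )
    for t in config.adjustment_traits:
        lp_survive = lp_survive + t.beta_s * traits[t.name]
    s = _bernoulli(rng, lp_survive)

    lp_y = (
        config.intercept_y
        + config.beta_xy * x
        + config.beta_u1y * u1
        + config.beta_u2y * u2
        + gx @ config.pleiotropy_zy
    )
    for t in config.adjustment_traits:
        lp_y = lp_y + t.beta_y * traits[t.name]
    y = _bernoulli(rng, lp_y)

    variant_ids = [f"x_v{i + 1}" for i in range(m)]
    instrument_of = ["x"] * m
    for t in config.adjustment_traits:
        variant_ids += [f"{t.name}_v{i + 1}" for i in range(t.n_variants)]
        instrument_of += [t.name] * t.n_variants
    n_total = len(variant_ids)

    return Cohort(
        genotypes=genotypes,
        variant_ids=variant_ids,
        effect_alleles=["A"] * n_total,
        other_alleles=["G"] * n_total,
        instrument_of=instrument_of,
        u1=u1,
        u2=u2,
        x=x,
        y2=y2,
        s=s,
        y=y,
        traits=traits,
    )


def select_survivors(cohort: Cohort) -> Cohort:
    """Restrict to individuals with ``s == 1``, preserving order.

    Raises ``ValueError`` if nobody survived: every downstream association
    scan would be undefined on an empty cohort.
    """
    mask = cohort.s == 1
    if not mask.any():
        raise ValueError("no survivors in cohort; association scans undefined")
    return cohort.take(np.flatnonzero(mask))


def apply_tabular_selection(
    cohort: Cohort,
    p_e: float,
    p_c: float,
    harmful_allele_carrier: Callable[[Cohort], np.ndarray] | None = None,
    potential_case: Callable[[Cohort], np.ndarray] | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> Cohort:
    """Kill a fraction ``p_e`` of harmful-allele carriers and ``p_c`` of potential cases.

    This is the literal mechanism the analytic odds-ratio correction assumes:
    the two death processes are treated as mutually exclusive, enforced by
    drawing a single uniform ``u`` per individual and partitioning
    ``[0, p_e)`` (exposure death, carriers only) and ``[p_e, p_e + p_c)``
    (competing-risk death, potential cases only).  An individual eligible for
    both therefore dies with probability exactly ``p_e + p_c``.

    Parameters
    ----------
    harmful_allele_carrier
        Predicate ``cohort -> bool array``; default: dose >= 1 at the first
        variant (the simulated effect allele is the harmful one).
    potential_case
        Predicate ``cohort -> bool array``; default: ``y == 1``.
    """
    if p_e < 0 or p_c < 0:
        raise ValueError("p_e and p_c must be >= 0")
    if p_e + p_c >= 1:
        raise ValueError("p_e + p_c must be < 1 (mutually exclusive death fractions)")
    if harmful_allele_carrier is None:
        harmful_allele_carrier = lambda c: c.genotypes[:, 0] >= 1  # noqa: E731
    if potential_case is None:
        potential_case = lambda c: c.y == 1  # noqa: E731
    if rng is None:
        rng = np.random.default_rng(seed)

    carrier = np.asarray(harmful_allele_carrier(cohort), dtype=bool)
    case = np.asarray(potential_case(cohort), dtype=bool)
    u = rng.random(cohort.n)
    dies = (carrier & (u < p_e)) | (case & (u >= p_e) & (u < p_e + p_c))
    return cohort.take(np.flatnonzero(~dies))


def simulate_carrier_outcome_cohort(
    n: int,
    maf: float,
    carrier_log_or: float,
    base_log_odds: float,
    seed: int | None = None,
) -> Cohort:
    """Minimal one-variant cohort whose outcome follows a dominant carrier model.

    ``logit P(Y=1) = base_log_odds + carrier_log_or * 1[dose >= 1]``.  Used by
    the mechanism-versus-formula consistency analysis, where the analytic
    correction's two-group (carrier vs non-carrier) structure is exact.
    All individuals start alive (``s = 1``); selection is applied afterwards
    with :func:`apply_tabular_selection`.
    """
    if not (0.0 < maf <= 0.5):
        raise ValueError("maf must lie in (0, 0.5]")
    rng = np.random.default_rng(seed)
    g = rng.binomial(2, maf, n).astype(np.int8)
    carrier = (g >= 1).astype(float)
    y = _bernoulli(rng, base_log_odds + carrier_log_or * carrier)
    zeros = np.zeros(n)
    return Cohort(
        genotypes=g[:, None],
        variant_ids=["v1"],
        effect_alleles=["A"],
        other_alleles=["G"],
        instrument_of=["x"],
        u1=zeros,
        u2=zeros,
        x=carrier,
        y2=np.zeros(n, dtype=np.int8),
        s=np.ones(n, dtype=np.int8),
        y=y,
    )


def write_cohort_tsv(cohort: Cohort, path) -> None:
    """Dump a cohort to tab-separated text, one row per individual."""
    import pandas as pd

    data = {f"g_{vid}": cohort.genotypes[:, j] for j, vid in enumerate(cohort.variant_ids)}
    data.update(u1=cohort.u1, u2=cohort.u2, x=cohort.x)
    for name, vals in cohort.traits.items():
        data[name] = vals
    data.update(y2=cohort.y2, s=cohort.s, y=cohort.y)
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.10g")


def _config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)

    def clean(obj):
        if isinstance(obj, np.ndarray):
            return [float(v) for v in obj]
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    return clean(d)


def config_to_yaml(config: SimulationConfig, path) -> None:
    """Write a scenario configuration as a structured text file (YAML)."""
    with open(path, "w") as fh:
        yaml.safe_dump(_config_to_dict(config), fh, sort_keys=False)


def config_from_yaml(path) -> SimulationConfig:
    """Read a scenario configuration written by :func:`config_to_yaml`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    traits = [AdjustmentTraitConfig(**t) for t in raw.pop("adjustment_traits", [])]
    return SimulationConfig(adjustment_traits=traits, **raw)
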