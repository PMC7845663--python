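"""End-to-end pipeline: simulate -> select -> scan -> harmonize -> MR -> report.

A *scenario* is one two-sample MR study run on synthetic data: an exposure
cohort and a disjoint outcome cohort are simulated from the same structural
model, survivor-selected, scanned per variant, harmonized, and analysed with
univariable IVW (primary-exposure instruments only) and multivariable MR
(primary plus shared-cause adjustment exposures, all instruments).  The
report mirrors the familiar side-by-side layout: univariable OR/CI versus
multivariable OR/CI with the Egger intercept, conditional F per exposure and
the multivariable Q p-value.

Shipped presets reproduce the causal diagrams this package studies:

``fig1a``
    valid MR — no selection, no pleiotropy;
``fig1b``
    directional pleiotropy, no selection;
``fig1c``
    survival directly on the instruments, shared etiology with the outcome;
``fig1d``
    survival on the instrumented exposure plus a competing disease sharing
    causes with the outcome — the competing-risk selection scenario;
``fig2b_statin_stroke``
    an LDL-lowering (statin-like) protective exposure against a stroke-like
    outcome with an IHD-like competing disease, adjusted for blood-pressure/
    smoking/BMI-like shared causes;
``fig2c_bmi_stroke``
    a harmful adiposity-like exposure with the same competing-risk wiring.

Preset effect sizes are illustrative: the phenomena they encode (harmful
exposures shortening survival, major shared causes of survival and outcome)
are qualitative in the source setting, so magnitudes were fixed once at
values that make the selection mechanism plainly visible at the default
sample size.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import mr_multi, mr_uni
from .bias_formula import SurvivalFractions, empirical_carrier_or, observed_or
from .simulate import (
    AdjustmentTraitConfig,
    SimulationConfig,
    apply_tabular_selection,
    select_survivors,
    simulate_carrier_outcome_cohort,
    simulate_cohort,
)
from .sumstats import association_scan, harmonize, prune_instruments

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioReport",
    "MonteCarloSummary",
    "PRESETS",
    "preset",
    "run_scenario",
    "replicate_study",
    "mechanism_consistency",
    "reports_to_frame",
    "render_report",
]


@dataclass
class ScenarioReport:
    """One scenario's side-by-side univariable / multivariable results."""

    scenario: str
    seed: int
    exposure: str
    outcome: str
    uni_or: float
    uni_ci_low: float
    uni_ci_high: float
    uni_beta: float
    uni_se: float
    uni_k: int
    mv_or: float
    mv_ci_low: float
    mv_ci_high: float
    mv_beta: float
    mv_se: float
    egger_intercept: float
    cond_f: dict[str, float]
    q_a: float
    q_pval: float
    k: int

    def __post_init__(self) -> None:
        if not (self.uni_ci_low < self.uni_or < self.uni_ci_high):
            raise ValueError("univariable CI must bracket its OR")
        if not (self.mv_ci_low < self.mv_or < self.mv_ci_high):
            raise ValueError("multivariable CI must bracket its OR")


@dataclass
class MonteCarloSummary:
    """Replicate-level aggregation of estimator behaviour against the truth."""

    n_reps: int
    n_failed: int
    true_beta: float
    mean_estimate: dict[str, float]
    mean_bias: dict[str, float]
    empirical_sd: dict[str, float]
    coverage: dict[str, float]
    mean_q_a: float
    prop_q_signif: float
    valid: bool = True

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        for v in self.coverage.values():
            if not (0.0 <= v <= 1.0):
                raise ValueError("coverage must lie in [0, 1]")


# ---------------------------------------------------------------------------
# presets

_N_DEFAULT = 50_000
_M_PRIMARY = 8
_M_ADJ = 8

#: mean-zero per-variant direct survival effects (log-odds of surviving) for
#: the selection presets: real instruments act on mortality through
#: variant-specific pathways, which is what makes selection show up as
#: heterogeneity (an inflated Q) and not merely as a shifted slope
_ZS_PATTERN = np.array([1.0, -1.0, 0.6, -0.6, 0.3, -0.3, 1.4, -1.4])


def _primary_block(beta_xy: float, **overrides) -> dict:
    base = dict(
        n_individuals=_N_DEFAULT,
        n_variants=_M_PRIMARY,
        maf=np.full(_M_PRIMARY, 0.3),
        beta_zx=np.linspace(0.08, 0.35, _M_PRIMARY),
        sd_u1=1.0,
        sd_u2=1.0,
        beta_u1x=0.3,
        noise_sd_x=1.0,
        intercept_y=-2.2,
        beta_xy=beta_xy,
        beta_u1y=0.2,
        beta_u2y=0.4,
        seed=0,
    )
    base.update(overrides)
    return base


def _shared_cause(name: str, beta_s: float) -> AdjustmentTraitConfig:
    return AdjustmentTraitConfig(
        name=name,
        maf=np.full(_M_ADJ, 0.3),
        beta_za=np.linspace(0.08, 0.35, _M_ADJ),
        beta_u2=0.6,
        beta_y2=1.0,
        beta_s=beta_s,
        beta_y=0.6,
        noise_sd=0.8,
    )


def _fig1a(n: int, seed: int) -> SimulationConfig:
    # valid MR: identical wiring to fig1d with every survival coefficient
    # zeroed out (and a positive true effect, log-OR 0.3)
    return SimulationConfig(
        **_primary_block(0.3, n_individuals=n, seed=seed, label="fig1a"),
        intercept_y2=-1.2, beta_xy2=-1.0, beta_u2y2=0.4,
        intercept_s=20.0,
        adjustment_traits=(_shared_cause("a1", 0.0), _shared_cause("a2", 0.0)),
    )


def _fig1b(n: int, seed: int) -> SimulationConfig:
    pleio = np.zeros(_M_PRIMARY)
    pleio[: _M_PRIMARY // 2] = 0.04  # directional pleiotropy on half the instruments
    return SimulationConfig(
        **_primary_block(0.3, n_individuals=n, seed=seed, label="fig1b"),
        intercept_y2=-1.2, beta_xy2=-1.0, beta_u2y2=0.4,
        intercept_s=20.0,
        pleiotropy_zy=pleio,
        adjustment_traits=(_shared_cause("a1", 0.0), _shared_cause("a2", 0.0)),
    )


def _fig1c(n: int, seed: int) -> SimulationConfig:
    # survival pressure directly on the instruments (one config field apart
    # from fig1d's exposure-mediated wiring), shared etiology via the traits
    return SimulationConfig(
        **_primary_block(-0.2, n_individuals=n, seed=seed, label="fig1c"),
        intercept_y2=-1.2, beta_xy2=0.0, beta_u2y2=0.4,
        intercept_s=0.6, beta_xs=0.0,
        beta_zs=np.full(_M_PRIMARY, 0.12) - 0.4 * _ZS_PATTERN,
        beta_y2s=0.0,
        adjustment_traits=(_shared_cause("a1", -1.0), _shared_cause("a2", -1.0)),
    )


def _fig1d(n: int, seed: int) -> SimulationConfig:
    # the competing-risk selection scenario: a protective (statin-like)
    # exposure lowers the competing disease, death and the outcome, so
    # survivors with low exposure are enriched for low shared-cause burden
    # and univariable MR sees the effect reversed; the shared-cause traits
    # a1/a2 carry most of the adjustable etiology while U2 keeps a residual
    # unadjustable share, and instruments carry variant-specific survival
    # pathways (mean-zero, so they perturb heterogeneity, not the slope)
    return SimulationConfig(
        **_primary_block(-0.2, n_individuals=n, seed=seed, label="fig1d"),
        intercept_y2=-1.2, beta_xy2=-1.0, beta_u2y2=0.4,
        intercept_s=0.6, beta_xs=1.0,
        beta_zs=-0.4 * _ZS_PATTERN,
        beta_y2s=-2.5,
        adjustment_traits=(_shared_cause("a1", -1.0), _shared_cause("a2", -1.0)),
    )


def _fig2b(n: int, seed: int) -> SimulationConfig:
    # as fig1d, with the shared causes named for the applied story
    return SimulationConfig(
        **_primary_block(-0.2, n_individuals=n, seed=seed, label="fig2b_statin_stroke"),
        intercept_y2=-1.2, beta_xy2=-1.0, beta_u2y2=0.4,
        intercept_s=0.6, beta_xs=1.0,
        beta_zs=-0.4 * _ZS_PATTERN,
        beta_y2s=-2.5,
        adjustment_traits=(
            _shared_cause("sbp", -1.0),
            _shared_cause("smoking", -1.0),
            _shared_cause("bmi", -0.6),
        ),
    )


def _fig2c(n: int, seed: int) -> SimulationConfig:
    # harmful adiposity-like exposure: raises the competing disease and death,
    # so survivor selection drags its apparent outcome effect toward the null
    return SimulationConfig(
        **_primary_block(0.2, n_individuals=n, seed=seed, label="fig2c_bmi_stroke"),
        intercept_y2=-1.2, beta_xy2=1.0, beta_u2y2=0.4,
        intercept_s=0.6, beta_xs=-1.0,
        beta_zs=-0.4 * _ZS_PATTERN,
        beta_y2s=-2.5,
        adjustment_traits=(_shared_cause("smoking", -1.0),),
    )


PRESETS = {
    "fig1a": _fig1a,
    "fig1b": _fig1b,
    "fig1c": _fig1c,
    "fig1d": _fig1d,
    "fig2b_statin_stroke": _fig2b,
    "fig2c_bmi_stroke": _fig2c,
}


def preset(name: str, n: int = _N_DEFAULT, seed: int = 0) -> SimulationConfig:
    """Build a shipped scenario configuration by name."""
    try:
        factory = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
    return factory(n, seed)


# ---------------------------------------------------------------------------
# pipeline


def _splice_cohorts(donor, other, n_shared: int):
    """Replace the first ``n_shared`` rows of ``other`` with rows of ``donor``."""
    from .simulate import Cohort

    def cat(a, b):
        return np.concatenate([a[:n_shared], b[n_shared:]], axis=0)

    return Cohort(
        genotypes=cat(donor.genotypes, other.genotypes),
        variant_ids=other.variant_ids,
        effect_alleles=other.effect_alleles,
        other_alleles=other.other_alleles,
        instrument_of=other.instrument_of,
        u1=cat(donor.u1, other.u1),
        u2=cat(donor.u2, other.u2),
        x=cat(donor.x, other.x),
        y2=cat(donor.y2, other.y2),
        s=cat(donor.s, other.s),
        y=cat(donor.y, other.y),
        traits={k: cat(donor.traits[k], v) for k, v in other.traits.items()},
    )


def run_scenario(
    config: SimulationConfig,
    adjustment_exposures: list[str] | None = None,
    seed: int = 0,
    outcome_id: str = "y",
    prune: bool = True,
    r2_threshold: float = 0.05,
    overlap_fraction: float = 0.0,
) -> ScenarioReport:
    """Simulate one two-sample study and analyse it end to end.

    Disjoint exposure and outcome cohorts are drawn from ``config`` with
    seeds spawned from ``seed`` (full pipeline determinism under a fixed
    seed), survivor-selected, scanned, harmonized, pruned and fed to the
    univariable and multivariable estimators.  ``overlap_fraction`` shares
    that fraction of individuals between the two samples (0 = strict
    two-sample design, 1 = one-sample).
    """
    if adjustment_exposures is None:
        adjustment_exposures = [t.name for t in config.adjustment_traits]
    unknown = set(adjustment_exposures) - {t.name for t in config.adjustment_traits}
    if unknown:
        raise ValueError(f"adjustment exposures not simulated in config: {sorted(unknown)}")
    if not (0.0 <= overlap_fraction <= 1.0):
        raise ValueError("overlap_fraction must lie in [0, 1]")

    ss = np.random.SeedSequence(seed)
    rng_exp, rng_out = (np.random.default_rng(c) for c in ss.spawn(2))

    try:
        exp_full = simulate_cohort(config, rng=rng_exp)
        out_full = simulate_cohort(config, rng=rng_out)
        n_shared = int(round(overlap_fraction * config.n_individuals))
        if n_shared:
            # the first n_shared outcome-sample rows are the same people as
            # in the exposure sample
            out_full = _splice_cohorts(exp_full, out_full, n_shared)
        exp_cohort = select_survivors(exp_full)
        out_cohort = select_survivors(out_full)
    except ValueError as err:
        logger.error("stage=simulate/select failed: %s", err)
        raise

    try:
        x_table = association_scan(exp_cohort, "x", "linear", sample_id="exposure_sample")
        adj_tables = [
            association_scan(exp_cohort, name, "linear", sample_id="exposure_sample")
            for name in adjustment_exposures
        ]
        y_table = association_scan(out_cohort, "y", "logistic", sample_id="outcome_sample")
    except ValueError as err:
        logger.error("stage=scan failed: %s", err)
        raise

    if prune:
        dosages = pd.DataFrame(
            exp_cohort.genotypes, columns=exp_cohort.variant_ids
        )
        kept: set[str] = set()
        for table, trait in [(x_table, "x")] + list(zip(adj_tables, adjustment_exposures)):
            own = [v for v, t in zip(exp_cohort.variant_ids, exp_cohort.instrument_of)
                   if t == trait and v in table.variant_ids]
            sub = table.df[table.df["variant_id"].isin(own)]
            from .sumstats import SummaryStatsTable
            pruned = prune_instruments(
                SummaryStatsTable(sub, trait_id=table.trait_id, sample_id=table.sample_id),
                dosages, r2_threshold=r2_threshold,
            )
            kept.update(pruned.variant_ids)

        def restrict(t):
            from .sumstats import SummaryStatsTable
            return SummaryStatsTable(t.df[t.df["variant_id"].isin(kept)],
                                     trait_id=t.trait_id, sample_id=t.sample_id)

        x_table = restrict(x_table)
        adj_tables = [restrict(t) for t in adj_tables]
        y_table = restrict(y_table)

    try:
        h = harmonize([x_table] + adj_tables, y_table)
    except ValueError as err:
        logger.error("stage=harmonize failed: %s", err)
        raise

    x_instruments = [
        v for v, t in zip(exp_cohort.variant_ids, exp_cohort.instrument_of)
        if t == "x" and v in h.variant_ids
    ]
    try:
        uni = mr_uni.ivw(h.subset(x_instruments).select_exposures(["x"]),
                         outcome_id=outcome_id)
        mv = mr_multi.mvmr(h)
    except (ValueError, np.linalg.LinAlgError) as err:
        logger.error("stage=mr failed: %s", err)
        raise

    j_primary = h.exposure_ids.index("x")
    return ScenarioReport(
        scenario=config.label or "custom",
        seed=seed,
        exposure="x",
        outcome=outcome_id,
        uni_or=uni.or_, uni_ci_low=uni.ci_low, uni_ci_high=uni.ci_high,
        uni_beta=uni.beta, uni_se=uni.se, uni_k=uni.k,
        mv_or=float(mv.or_[j_primary]),
        mv_ci_low=float(mv.ci_low[j_primary]),
        mv_ci_high=float(mv.ci_high[j_primary]),
        mv_beta=float(mv.theta[j_primary]),
        mv_se=float(mv.se_theta[j_primary]),
        egger_intercept=mv.egger_intercept,
        cond_f={e: float(f) for e, f in zip(mv.exposure_ids, mv.cond_f)},
        q_a=mv.q_a,
        q_pval=mv.q_pval,
        k=mv.k,
    )


def replicate_study(
    config: SimulationConfig,
    adjustment_exposures: list[str] | None = None,
    n_reps: int = 200,
    seed: int = 0,
    true_beta: float | None = None,
) -> tuple[MonteCarloSummary, list[ScenarioReport]]:
    """Monte-Carlo replication of :func:`run_scenario`.

    Per-replicate seeds are spawned reproducibly from the master seed.
    Failed replicates are recorded and excluded; a failure rate above 10%
    marks the whole run invalid.  The truth defaults to the config's
    conditional exposure-on-outcome log-odds coefficient.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if true_beta is None:
        true_beta = config.beta_xy
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                   np.random.SeedSequence(seed).spawn(n_reps)]
    reports: list[ScenarioReport] = []
    n_failed = 0
    for rep_seed in child_seeds:
        try:
            reports.append(run_scenario(config, adjustment_exposures, seed=rep_seed))
        except (ValueError, np.linalg.LinAlgError, ZeroDivisionError) as err:
            n_failed += 1
            logger.warning("replicate with seed %d failed: %s", rep_seed, err)
    if not reports:
        raise RuntimeError("all replicates failed")
    summary = summarize_reports(reports, n_reps=n_reps, n_failed=n_failed,
                                true_beta=true_beta)
    return summary, reports


def summarize_reports(reports: list[ScenarioReport], n_reps: int, n_failed: int,
                      true_beta: float) -> MonteCarloSummary:
    """Aggregate scenario reports into a Monte-Carlo summary."""
    uni = np.array([r.uni_beta for r in reports])
    uni_se = np.array([r.uni_se for r in reports])
    mv = np.array([r.mv_beta for r in reports])
    mv_se = np.array([r.mv_se for r in reports])
    q = np.array([r.q_a for r in reports])
    qp = np.array([r.q_pval for r in reports])

    Z95 = mr_uni.Z95

    def cov(est, se):
        return float(np.mean((est - Z95 * se <= true_beta) & (true_beta <= est + Z95 * se)))
    return MonteCarloSummary(
        n_reps=n_reps,
        n_failed=n_failed,
        true_beta=true_beta,
        mean_estimate={"univariable": float(uni.mean()), "multivariable": float(mv.mean())},
        mean_bias={"univariable": float(uni.mean() - true_beta),
                   "multivariable": float(mv.mean() - true_beta)},
        empirical_sd={"univariable": float(uni.std(ddof=1)),
                      "multivariable": float(mv.std(ddof=1))},
        coverage={"univariable": cov(uni, uni_se), "multivariable": cov(mv, mv_se)},
        mean_q_a=float(q.mean()),
        prop_q_signif=float(np.mean(qp < 0.05)),
        valid=n_failed <= 0.1 * n_reps,
    )


# ---------------------------------------------------------------------------
# mechanism vs analytic formula


def mechanism_consistency(
    n: int = 1_000_000,
    maf: float = 0.3,
    or_true: float = 0.96,
    p_e: float = 0.10,
    p_c: float = 0.40,
    base_log_odds: float = -1.4,
    seed: int = 1,
) -> dict[str, float]:
    """Simulated tabular selection versus the analytic observed-OR prediction.

    Simulates a one-variant cohort with a dominant carrier effect whose
    protective-coded (non-carrier vs carrier) true OR is ``or_true``, applies
    the literal table mechanism with fractions ``(p_e, p_c)``, and compares
    the survivor 2x2 odds ratio with :func:`survivormr.bias_formula.observed_or`.
    Returns the empirical OR, its Monte-Carlo SE on the log scale, the
    predicted OR, and their distance in Monte-Carlo SEs.
    """
    ss = np.random.SeedSequence(seed)
    s_sim, s_sel = ss.spawn(2)
    # protective-coded OR or_true means carriers of the harmful allele have
    # log-odds higher by -log(or_true)
    cohort = simulate_carrier_outcome_cohort(
        n=n, maf=maf, carrier_log_or=-math.log(or_true),
        base_log_odds=base_log_odds, seed=s_sim,
    )
    survivors = apply_tabular_selection(
        cohort, p_e=p_e, p_c=p_c, rng=np.random.default_rng(s_sel)
    )
    or_emp, se_log = empirical_carrier_or(survivors.genotypes[:, 0] >= 1,
                                          survivors.y == 1)
    or_pred = observed_or(or_true, SurvivalFractions(p_e, p_c))
    z = abs(math.log(or_emp) - math.log(or_pred)) / se_log
    return {
        "or_empirical": or_emp,
        "se_log_or": se_log,
        "or_predicted": or_pred,
        "z_distance": z,
        "n_survivors": survivors.n,
    }


# ---------------------------------------------------------------------------
# reporting


def reports_to_frame(reports: list[ScenarioReport]) -> pd.DataFrame:
    """Flatten scenario reports into a table mirroring the familiar layout."""
    rows = []
    for r in reports:
        row = {
            "scenario": r.scenario, "seed": r.seed, "exposure": r.exposure,
            "outcome": r.outcome,
            "uni_OR": r.uni_or, "uni_CI_low": r.uni_ci_low, "uni_CI_high": r.uni_ci_high,
            "mv_OR": r.mv_or, "mv_CI_low": r.mv_ci_low, "mv_CI_high": r.mv_ci_high,
            "egger_intercept": r.egger_intercept,
            "q_pval": r.q_pval, "k": r.k,
        }
        for name, f in r.cond_f.items():
            row[f"cond_F_{name}"] = f
        rows.append(row)
    return pd.DataFrame(rows)


def render_report(report: ScenarioReport) -> str:
    """Plain-text one-scenario table in the univariable/multivariable layout."""
    cf = ", ".join(f"{k}={v:.1f}" for k, v in report.cond_f.items())
    lines = [
        f"scenario: {report.scenario} (seed {report.seed})",
        f"exposure: {report.exposure}   outcome: {report.outcome}   variants: {report.k}",
        "",
        f"{'':<16}{'OR':>8}{'95% CI':>18}",
        f"{'univariable':<16}{report.uni_or:>8.2f}"
        f"{f'{report.uni_ci_low:.2f}-{report.uni_ci_high:.2f}':>18}",
        f"{'multivariable':<16}{report.mv_or:>8.2f}"
        f"{f'{report.mv_ci_low:.2f}-{report.mv_ci_high:.2f}':>18}",
        "",
        f"MR-Egger intercept: {report.egger_intercept:.3f}",
        f"conditional F: {cf}",
        f"Q p-value: {report.q_pval:.3g}",
    ]
    return "\n".join(lines)
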