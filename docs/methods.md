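# Methods

## The structural model

`survivormr.simulate` draws individual-level data from a directed acyclic
graph designed around survivor selection under competing risk:

* biallelic variants `Z` in linkage equilibrium, dose-coded 0/1/2 with
  configurable minor-allele frequencies, instrumenting a continuous primary
  exposure `X = Z·β_zx + β_u1x·U1 + ε`;
* a confounder `U1 ~ N(0, σ²_u1)` of exposure and outcome;
* *shared-cause traits* `A_t = Z_t·β_za + λ_t·U2 + ε_t` — heritable analogues
  of blood pressure, smoking or adiposity, each with its own independent
  instruments, mutually correlated through a latent factor `U2`;
* a binary competing disease `Y2` (logistic in `X`, the `A_t` and `U2`);
* survival to recruitment `S`, Bernoulli with logistic link on the log-odds
  of *surviving*: intercept plus contributions from `X` (or directly from
  each variant via the per-variant vector `β_zs`), from `Y2`, and from the
  shared-cause traits;
* the binary outcome `Y` (logistic in `X`, `U1`, `U2`, the `A_t`, and any
  direct variant effects `pleiotropy_zy`).

All binary traits use the logistic link so every reported effect lives on
the odds-ratio scale.  Association scans are run on survivors only, which
conditions on a collider between the instruments and the shared causes of
the outcome.

Two design points deserve emphasis:

**Adjustment exposures are shared causes, not passive proxies.**  For
multivariable adjustment to block the selection-induced backdoor path, the
adjustment exposures must carry causal effects on survival and on the
outcome — as blood pressure, smoking and BMI do.  A trait that is merely a
noisy child of `U2` has null variant-outcome effects, so the contaminated
outcome associations of the primary instruments cannot be attributed to it
and multivariable MR would remove nothing.  The simulator therefore gives
each adjustment trait its own effects on the competing disease, on survival
and on the outcome, with correlation among traits induced by the latent
`U2`; a residual direct `U2 → Y` path represents the share of etiology that
no measured trait captures.

**Why the Q-statistic sees selection.**  If every instrument of an exposure
is contaminated in proportion to its effect on that exposure, the
contamination is absorbed into the multivariable slope as pure bias and the
Q-statistic stays at its degrees of freedom — a block-structured graph
cannot inflate Q, only shift estimates.  Real instruments, however, act on
mortality through variant-specific pathways.  The selection presets encode
this as a mean-zero per-variant pattern of direct survival effects
(`β_zs`), so selection perturbs different instruments differently; the
resulting within-class heterogeneity is exactly what the multivariable
Q-statistic detects, while the mean-zero pattern leaves the slope bias
essentially unchanged.  This reproduces, in a controlled setting, the use of
an inflated multivariable Q as a selection-bias signal and a calm Q as
evidence that adjustment succeeded.

## Selection mechanisms

`select_survivors` restricts a cohort to `S = 1` (raising on an empty
selection).  `apply_tabular_selection` implements the literal two-fraction
mechanism the analytic correction assumes: one uniform draw per individual
partitioned into `[0, p_e)` (death attributable to the genetically
predicted exposure; harmful-allele carriers only) and `[p_e, p_e + p_c)`
(death of potential outcome cases from competing risk), which enforces
mutually exclusive deaths and requires `p_e + p_c < 1`.

## The analytic correction

Survival probabilities by (carrier, case) cell are `1 - p_e - p_c`,
`1 - p_e`, `1 - p_c` and `1`.  With the odds ratio coded for the protective
allele, the observed OR among survivors equals the true OR times
`(1 - p_e)(1 - p_c) / (1 - p_e - p_c)`; `corrected_or` applies the exact
inverse and `reversal_fraction` solves in closed form for the `p_c` that
drags a protective OR to exactly 1 (no reversal exists at `p_e = 0`, where
the two genotype groups lose cases at the same rate).  The derivation is a
2×2 (carrier versus non-carrier) argument, so the mechanism–formula
consistency check simulates a dominant carrier effect and compares the
survivor 2×2 odds ratio with the prediction; a per-dose logistic slope does
not equal the two-group prediction when selection acts on carrier status,
because the survivor dose–response is a step function between dose 0 and
dose ≥ 1.  The correction is derived for an observed OR above 1; applying
it below 1 is permitted but warned about.

## Estimators

* **Wald ratio** `by/bx` with first-order delta SE `|se_by/bx|` (exposure-side
  uncertainty ignored, the convention of summary-statistics IVW); a
  second-order SE is available behind a flag.
* **Univariable IVW** with multiplicative random effects: weights `1/se_i²`,
  dispersion `max(1, √(Q/(k-1)))` scaling the fixed-effect SE, so
  heterogeneity can only widen intervals.  95% intervals use the normal
  quantile.  The algebraically identical zero-intercept weighted regression
  (`ivw_regression`) is implemented and tested equal — it is the K = 1
  reduction of the multivariable estimator.
* **Multivariable IVW**: weighted no-intercept least squares of `by` on the
  `k × K` exposure-effect matrix, weights `1/se_by²`; SEs from the inverse
  weighted normal-equations matrix scaled by `max(1, √(wRSS/(k-K)))`.  The
  overdispersion uses the fit's own weighted residual sum of squares so the
  K = 1 case coincides exactly with the univariable regression form; the
  exposure-uncertainty-propagating Q below is reported separately as the
  diagnostic.
* **Multivariable Q**: `Σ (by - bx·θ)² / (se_by² + Σ_j θ_j² se_bx_j²)`
  against χ²(k−K), zero covariance between exposure estimates assumed
  (non-overlapping exposure samples), under which the Q is an upper bound on
  pleiotropy/selection heterogeneity.  Plug-in θ by default; an iterated
  fixed point (re-estimating θ under the augmented weights, tolerance 1e-8,
  at most 100 iterations) is available and agrees closely when instruments
  are strong.
* **Conditional F** per exposure: for K = 1 the mean per-variant χ²; for
  K ≥ 2 the weighted residual sum of squares from regressing that exposure's
  effects on the other exposures' effects (weights `1/se_bx²`, no
  intercept), divided by `k − K + 1`.  A lower bound on instrument strength
  under the zero-covariance assumption.  All K values are reported and
  labelled, since a single table cell cannot summarise K exposures.
* **Multivariable MR-Egger**: rows sign-flipped so the orientation exposure
  (first-listed by default, configurable) has non-negative effects, then
  weighted least squares *with* intercept; intercept SE carries the
  multiplicative overdispersion with `k − K − 1` degrees of freedom and a
  two-sided normal p-value.

Per-variant scans are vectorised closed-form OLS (continuous traits) and
vectorised two-parameter Newton/IRLS logistic fits (binary traits,
convergence tolerance 1e-8, at most 60 iterations); monomorphic variants
and non-converged or separated fits are dropped with a logged warning.
Scans are unadjusted, as public GWAS summary statistics effectively are
from this package's perspective.  Harmonization aligns every table on the
first exposure table's effect allele (flip: `β → −β`, `eaf → 1 − eaf`),
resolves strand flips by complement, resolves palindromic variants by
allele-frequency proximity when both frequencies are at least 0.08 from
0.5, and drops irreconcilable variants with a log message.  Instrument
pruning is greedy by ascending p-value with an r² < 0.05 acceptance rule
against a dosage reference.

## The pipeline and its presets

`run_scenario` simulates disjoint exposure and outcome cohorts (a strict
two-sample design; the exposure cohort supplies all exposure scans, as a
biobank would), survivor-selects both, scans, prunes, harmonizes, and runs
univariable IVW on the primary-exposure instruments and multivariable MR on
all instruments.  `replicate_study` repeats this with seed-sequence-spawned
per-replicate seeds, excludes and counts failed replicates (more than 10%
failures marks the run invalid), and aggregates mean estimates, bias,
empirical SD, 95% CI coverage, mean Q and the share of significant Q tests.

Shipped presets encode the canonical diagrams: valid MR (`fig1a`),
directional pleiotropy (`fig1b`), survival directly on the instruments
(`fig1c`), survival on the exposure with a competing disease and shared
causes (`fig1d`), and applied variants (`fig2b_statin_stroke`,
`fig2c_bmi_stroke`).  Survival-effect magnitudes are nowhere quantified in
the setting the presets emulate, so they are deliberately illustrative:
chosen once, via short pilot screens at a fixed master seed, to make the
mechanism plainly visible at the default sample size (50 000 per cohort,
8 instruments per exposure, two shared-cause traits; about 35% of the
selection-preset cohort survives to recruitment — an exaggerated mortality
that trades realism for a clear signal).  In the frozen `fig1d` preset a
true OR of 0.82 per exposure unit yields a mean univariable OR near 1.09
and a mean multivariable OR near 0.91 over 200 replicates, with mean
multivariable Q about 24 against 21 degrees of freedom (the no-selection
control sits at 21).

## What the synthetic data do and do not emulate

The generator reproduces the two-sample summary-statistics workflow:
per-variant effect estimates with allele metadata, allele flips,
survivor-selected samples, heritable correlated exposures.  It does not
emulate linkage disequilibrium (variants are independent; pruning is
exercised on constructed duplicates), covariate-adjusted GWAS models,
age-structured or time-to-event mortality, or realistic allele-frequency
spectra; sample overlap between the exposure and outcome studies is
available only as a crude row-sharing fraction (`overlap_fraction`, default
0 for the strict two-sample design).  Passing tests therefore demonstrate
the estimators' algebra, calibration under correct specification, and the
selection mechanism's direction and magnitude *within this model family* —
not the size of the bias in any particular real study.

## Numerical choices and degenerate inputs

Normal 95% quantile (1.96) throughout; χ² reference distributions with
`k − 1` (univariable Q), `k − K` (multivariable Q and IVW overdispersion)
and `k − K − 1` (Egger) degrees of freedom.  Dispersion factors are floored
at 1.  A Wald ratio with `bx = 0` raises; a rank-deficient exposure matrix
raises naming the collinear exposures; Egger with all orientation effects
zero raises; `k ≤ K` (or `k ≤ K + 1` for Egger) raises; the combined report
degrades Egger to NaN when variants are too few rather than failing the
whole analysis.  Ties in pruning are broken by input order (stable sort on
p-value).  Round-trip summary-statistics I/O is exact to at least 10
significant digits (`%.12g`).

## Known limitations

Logistic non-collapsibility means the estimand of summary-statistics MR
with a binary outcome is the marginal per-exposure-unit log-OR, attenuated
relative to the conditional simulation coefficient; coverage is therefore
evaluated against the marginal estimand (computed by running the estimator
at very large n), and effect-recovery checks use generous tolerances.  The
analytic correction assumes independent, mutually exclusive death
processes and a binary exposure contrast; it is a sensitivity-analysis
device, not an estimator.  Conditional F and multivariable Q assume zero
covariance between exposure-effect estimates, which overlapping exposure
GWAS would violate.
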