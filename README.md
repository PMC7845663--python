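# survivormr

Selection bias from survival to recruitment in Mendelian randomization (MR)
under competing risk — a simulation laboratory, two-sample MR estimators with
diagnostics, and the analytic odds-ratio correction that quantifies the bias.

## The problem

Genetic instruments are fixed at conception, but participants of GWAS of
late-onset diseases are recruited in middle or old age.  A study of, say,
lipid-lowering on stroke therefore recruits only people who survived both
their genetically predicted lipid levels *and* competing risk of earlier
death from ischemic heart disease, which shares causes (blood pressure,
smoking, adiposity) with stroke.  Recruiting survivors conditions on a
collider between the instrument and those shared causes, violating the
exclusion restriction: univariable MR can attenuate or even reverse the
effect of a protective exposure.  This package provides three connected
tools for studying and handling that bias:

1. **`survivormr.simulate`** — a structural causal simulator (instruments →
   exposure → competing disease → survival; shared causes of survival and
   outcome) that manufactures the bias, plus the literal "kill a fraction
   p_e of harmful-allele carriers and p_c of potential cases" selection
   mechanism.
2. **`survivormr.sumstats` / `mr_uni` / `mr_multi`** — GWAS-style per-variant
   scans, allele harmonization, greedy r² pruning, Wald-ratio IVW with
   multiplicative random effects, and multivariable MR with the conditional
   F-statistic, multivariable Q-statistic and MR-Egger intercept.
   Multivariable MR adjusted for major shared causes of survival and outcome
   ameliorates the bias; the Q-statistic flags what remains.
3. **`survivormr.bias_formula`** — the analytic correction.  With the odds
   ratio expressed for the protective allele, death fractions p_e (exposed
   carriers) and p_c (potential cases) inflate a true OR to

   ```
   OR_obs = OR_true * (1 - p_e)(1 - p_c) / (1 - p_e - p_c)
   ```

   and the correction is the exact inverse: the observed OR times the ratio
   of the probability of surviving the exposure *and* the competing risk
   (mutually exclusive deaths) to the probability of surviving either under
   independence.

## Worked example

```python
>>> from survivormr import SurvivalFractions, observed_or, corrected_or, reversal_fraction
>>> observed_or(0.96, SurvivalFractions(p_e=0.10, p_c=0.25))
0.9969230769230769        # a true 0.96 looks exactly null (1.00 at 2 dp)
>>> observed_or(0.96, SurvivalFractions(p_e=0.10, p_c=0.40))
1.0368000000000002        # ... and reverses to 1.04 at heavier competing risk
>>> corrected_or(1.04, SurvivalFractions(p_e=0.10, p_c=0.40))
0.9629629629629629        # the correction recovers 0.96
>>> reversal_fraction(0.96, p_e=0.10)
0.2647058823529414        # p_c at which the observed OR is exactly 1
```

The pipeline end to end (`analysis/03_replication_study.py`, 200 Monte-Carlo
replicates per scenario, ~2 minutes) prints:

```
fig1a: uni mean OR 1.241, mv mean OR 1.242 (true 1.350), mean Q 21.2
fig1d: uni mean OR 1.091, mv mean OR 0.912 (true 0.819), mean Q 23.8
```

In the valid-MR control (`fig1a`) univariable and multivariable estimates
agree (both slightly attenuated toward the null by logistic
non-collapsibility) and the multivariable Q sits at its degrees of freedom
(21).  In the competing-risk selection scenario (`fig1d`) a protective
exposure (true OR 0.82) is *reversed* by univariable MR (mean OR 1.09) while
multivariable MR adjusted for the shared causes of survival and outcome
recovers the protective direction (mean OR 0.91), with the residual
inflation of the Q-statistic signalling the remaining selection
heterogeneity.

The numbered scripts under `analysis/` are thin drivers over the library:
`01_worked_example.py` (the formula and a sensitivity grid),
`02_mechanism_check.py` (simulated tabular selection versus the analytic
prediction at n = 10⁶), `03_replication_study.py` (the replication above).
Each writes tab-separated tables under `results/`.

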