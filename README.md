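# ltfimpute

Estimating 10-year vital status and predictors of death in an HIV treatment
cohort when a substantial fraction of patients is **lost to follow-up (LTF)**
— no documented death or transfer, no recent clinic contact, vital status
unknown. LTF is missing data on the outcome, not an outcome itself: treating
it as censoring or dropping it biases both survival estimates and odds
ratios. This package implements, on a common cohort interface, the four
standard answers and makes them comparable:

- **Complete case (CC)** — drop patients with missing outcome/covariates;
  Kaplan–Meier survival with the lost censored at their last visit.
- **Inverse probability weighting from tracing (IPW)** — actively trace the
  lost, extrapolate the death risk found among them, and weight each complete
  case by 1/P(being a complete case) in its outcome stratum (with a 1/f
  correction when only a fraction f is found).
- **MICE** — multiple imputation by chained equations of missing covariates
  (predictive mean matching, 5 donors) and the missing binary vital status
  (logistic posterior draws) *simultaneously*, M = 20 imputations pooled by
  Rubin's rules: pooled estimate q̄ = mean of the M estimates, total variance
  T = W + (1 + 1/M)B with W the mean within-imputation variance and B the
  between-imputation variance, Barnard–Rubin degrees of freedom.
- **MICE-then-delete** — impute everything, then delete rows whose outcome
  was imputed before fitting (a sensitivity analysis).

It is aimed at epidemiologists and biostatisticians analysing retention and
mortality in cohorts with informative attrition. Because real clinic data of
this kind are rarely shareable, the package ships a synthetic cohort
generator with known ground truth (910 adults, realistic covariate marginals,
a configurable missing-at-random or outcome-dependent loss mechanism, and an
outcome-tracing step), so every estimator is validated by parameter recovery.
See `docs/methods.md` for the models and conventions.

## Worked example

```python
import ltfimpute as lt

model = lt.LtfCohortModel.simulate(seed=7)      # synthetic cohort + tracing
res = model.fit(method="mice", spec=lt.ImputationSpec(m=20, seed=7))
print(res.summary())
```

```
Vital-status analysis (mice)
--------------------------------------------
N (multivariable model): 910
Survival at 10 years: 72.3% (95% CI 69.3% - 75.4%)

Adjusted odds ratios for death by 10 years
term                     OR    2.5%   97.5%
female                 0.90    0.64    1.27
age_years              1.37    1.17    1.60
severe_poverty         1.98    1.44    2.73
residence_pap          1.13    0.81    1.58
weight_kg              0.73    0.61    0.87
cd4                    0.91    0.85    0.98
who_stage_advanced     1.54    1.12    2.11
tb_baseline            1.38    0.89    2.12
```

All 910 patients contribute (the point of imputing rather than dropping).
Odds ratios are per 10 years of age, per 10 kg of weight and per 100 CD4
cells: death odds rise with age, poverty and advanced WHO stage and fall
with higher baseline weight and CD4 — and the pooled estimates sit close to
the generating coefficients of the simulation (e.g. poverty OR 1.98 against
a generating value of 1.80, inside the 95% CI).

Running all four methods side by side:

```python
report = model.compare(spec=lt.ImputationSpec(m=20, seed=7))
print(report.summary())
```

```
Comparison of vital-status estimation methods
==============================================

Survival at 10 years
  complete_case       73.5%  (95% CI 70.6% - 76.5%)
  ipw                 72.0%  (95% CI 68.9% - 75.0%)
  mice                72.3%  (95% CI 69.3% - 75.4%)
  mice_then_delete    72.6%  (95% CI 69.6% - 75.6%)

Multivariable odds ratios for death by 10 years
method              complete_case   ipw  mice  mice_then_delete
term                                                           
age_years                    1.34  1.34  1.37              1.37
cd4                          0.92  0.92  0.91              0.91
female                       0.84  0.84  0.90              0.90
residence_pap                1.06  1.06  1.13              1.12
severe_poverty               2.07  2.07  1.98              1.97
tb_baseline                  1.16  1.16  1.38              1.34
weight_kg                    0.70  0.70  0.73              0.73
who_stage_advanced           1.52  1.52  1.54              1.54
```

Under the default missing-at-random loss the four methods agree closely;
the Kaplan–Meier estimate sits highest because censoring the lost at their
last visit assumes they fare like the retained. Flip the generator's MNAR
switch (`LtfModel(outcome_coef=...)`) to make the truly dead likelier to be
lost and the gap widens — the tested bias ordering.

The same pipeline is available from the shell:

```bash
ltfimpute simulate --seed 7 --out runs/sim
ltfimpute compare --observed runs/sim/observed.csv \
                  --tracing runs/sim/tracing.csv --seed 7 --out runs/report
```

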