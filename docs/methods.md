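# Methods

## The problem

In HIV treatment cohorts a sizeable fraction of patients ends follow-up as
"lost to follow-up" (LTF): no documented death or transfer and no clinic or
pharmacy contact in the last 180 days. LTF is not an outcome — it is missing
data on the binary outcome of interest, vital status at 10 years. This
package implements and compares four ways of analysing 10-year mortality and
its baseline predictors under that missingness:

1. **Complete case (CC)** — drop every row with a missing outcome, and drop
   rows with missing covariates per model. Kaplan–Meier survival with the lost
   censored at their last visit is the companion survival estimate.
2. **Inverse probability weighting from tracing (IPW)** — actively traced LTF
   patients whose status is resolved are used to (a) extrapolate the death
   risk to all the lost and (b) reweight complete cases by
   1/P(complete case) within outcome strata. Never-found patients remain
   excluded.
3. **MICE** — multiple imputation by chained equations of the missing
   covariates (predictive mean matching) *and* the missing vital status
   (logistic posterior draw) simultaneously, pooled by Rubin's rules.
4. **MICE-then-delete** — a sensitivity analysis: impute everything, then
   delete the rows whose outcome was imputed before fitting.

Because the underlying clinic data are not public, the package ships a
synthetic cohort generator with known ground truth; every estimator is tested
by parameter recovery against the generating model rather than against a
deposited dataset.

## Synthetic cohort generator

`GeneratorConfig` defaults describe a cohort of 910 adults starting ART and
followed ten years.

Covariate marginals (units in parentheses; each chosen to match the emulated
cohort's published medians/IQRs where available, otherwise set once to values
typical of early ART cohorts in the region):

| covariate | default distribution |
|---|---|
| female | Bernoulli(0.58) |
| age (years) | Normal(36, 10), truncated at 13 |
| severe poverty (<1 USD/day) | Bernoulli(0.50) |
| Port-au-Prince residence | Bernoulli(0.62) |
| weight (kg) | Normal by sex: men 56 (SD 9.6), women 49 (SD 8.9), floor 25 |
| CD4 (cells/µL) | Lognormal, median 131, log-SD 1.06, capped at 1500 |
| advanced WHO stage | Bernoulli(0.55) |
| baseline TB | Bernoulli(0.16) |

The CD4 log-SD comes from matching the quoted IQR (51–212) of a lognormal;
the weight SDs from the sex-specific IQRs (50–63, 44–56) of a normal.

**Outcome model.** True death by 10 years is logistic on the clinically
scaled covariates (age/10 yr, weight/10 kg, CD4/100 cells) with default
coefficients equal to the log odds ratios of the adjusted mortality model the
cohort motivates (female 0.62, age 1.37, residence 1.18, poverty 1.80, CD4
0.91, weight 0.66, WHO stage 1.76, TB 1.61, on the OR scale). The intercept
is calibrated at generation time by root-finding so that the model-implied
marginal death probability over the simulated covariates equals
`marginal_death` (default 0.29 ≈ documented deaths plus the extrapolated
deaths among the lost). Death times are drawn with decreasing density over
follow-up (10·u^1.6 for uniform u), reflecting front-loaded early mortality
after ART start; the generator is cross-sectional at 10 years, so the exact
hazard shape only matters for the Kaplan–Meier curve.

**Observation model.** LTF is logistic on covariates (slopes: poverty +0.25,
CD4 −0.15 per 100, age −0.10 per 10 yr, WHO +0.15 — sicker and poorer
patients are lost slightly more often) with the intercept calibrated to a
marginal LTF fraction of 0.12. An `outcome_coef` term on the true outcome is
the MNAR switch; its default of 0 makes loss missing-at-random given
covariates, the assumption all three correction methods rely on. Baseline
weight and CD4 are masked completely at random at 3% and 12%. Transfers
(assumed alive at 10 years, hence outcome-observed) are drawn among truly
alive, non-lost patients at rate 0.13, giving ≈8% of the cohort. LTF
last-visit times are uniform over follow-up (truncated at the death time for
the covertly dead); no loss-time distribution is reported for the emulated
cohort, so uniform is the deliberate neutral choice.

**Tracing.** Every LTF patient is traced; success is Bernoulli with base
probability 0.29, optionally tilted on the log-odds scale by
`recency_coef × (last_visit − 5)` so the recently lost are easier to find.
The default keeps success uniform: the recency effect is a robustness lever,
not part of the reference conditions. Found patients report their true
status.

What the generator deliberately does **not** emulate: visit-level
longitudinal records, time-varying covariates, ART regimen switches,
re-engagement after loss, and measurement error in covariates. Passing tests
therefore demonstrate correctness of the estimators under a clean MAR/MNAR
mechanism, not robustness to every feature of real clinic data.

## Tracing arithmetic and IPW

`estimate_ltf_deaths` extrapolates the traced death fraction to all the lost;
the estimated death count uses round-half-up (156 × 8/45 → 28).
`stratum_ipw_weights` computes P(complete case) per outcome stratum as
known/(known + estimated); weights are reciprocals, and the calibration
identity weight × P(complete) = 1 holds per stratum. When only a fraction *f*
of the lost is traced, each traced case carries weight 1/*f* in the
completeness model (equivalent to duplicating each traced record 1/*f*
times, which is how the property is tested). The default pipeline uses the
outcome-stratum weights; `covariate_ipw_weights` exposes the
covariate-conditional variant, as a logistic completeness model or — for
purely categorical covariates, where cells with completeness exactly 1 push
the logistic MLE to infinity — as a saturated cell-proportion estimate.

Two conventions worth flagging:

- Stratum weights are computed from the *tracing-folded* known counts against
  the estimate extrapolated over *all* originally lost patients. This mirrors
  the published arithmetic (482 known alive vs 128 estimated alive among 156
  LTF → 0.79) even though the found-alive appear on both sides; the
  alternative (never-found only in the denominator) differs by <1% here.
- The weight for known-dead patients uses the symmetric stratum formula; the
  source arithmetic only states the known-alive weight.

## Logistic regression

`logistic_fit` is plain IRLS maximum likelihood. It is written in-package
rather than delegated because the chained-equation engine performs thousands
of small conditional fits per run and because the test suite pins it to a
closed-form oracle on all small 2×2 tables at 1e-8; statsmodels GLM serves
as an independent cross-check in the tests. With weights the covariance
defaults to the design-based sandwich with squared weighted scores (the
Stata pweight convention) — model-based standard errors are anti-conservative
under inverse-probability weighting. Note this differs from frequency-weight
robust variances, which scale the meat by w rather than w²; the test suite
validates the choice against the Monte-Carlo sampling SD of the weighted
estimator. Separation is detected by non-convergence or |β| > 30 and raised
as an error with diagnostics, never returned silently.

Reported odds ratios are per 10 years of age, 10 kg of weight and 100 CD4
cells; `scale_covariates` applies the rescaling once and flags the frame so a
second application raises instead of silently rescaling.

## Chained-equation imputation

Defaults: M = 20 imputations, k = 5 PMM donors, 10 cycles of burn-in per
stream. The cycle count is configurable; ten cycles is comfortably past where
the chain-mean trend statistic goes flat on cohorts of this size.

- **Visit order** is fixed (weight, CD4, vital status): ascending
  missingness, alphabetical tie-break.
- **Conditional models.** Each variable's model includes all fully observed
  covariates, the other imputed variables, and the outcome; polynomial terms
  (weight², CD4³, the transforms retained from fractional-polynomial
  selection on complete cases) enter as predictors but are **passively
  imputed** — recomputed from the imputed raw variable after every update —
  never imputed independently, so completed data stay functionally
  consistent. The cubic is the single term (cd4/100)³ alongside the linear
  term, not a full fractional-polynomial basis; likewise weight enters as
  (weight/10) and (weight/10)².
- **PMM** (type-1 matching): coefficients drawn from the approximate
  posterior (σ² from its scaled inverse-χ², β from a normal around the MLE),
  missing-row predictions from the draw, donor predictions from the
  posterior-mean fit, one of the k nearest donors by absolute predicted-value
  distance copied, ties broken by donor index after a seeded shuffle. PMM
  guarantees imputed values are observed values, hence range preservation.
- **Binary outcome**: logistic fit on outcome-observed rows, normal posterior
  perturbation of the coefficients, Bernoulli draw. Transfers enter as
  observed-alive; the lost enter with the outcome missing.
- **Initialisation**: random draws from each variable's observed marginal.
- **Reproducibility**: one `SeedSequence` child per imputation stream;
  identical (data, spec, seed) reproduce the `ImputationSet` bit for bit.
- **Guards**: a conditional fit that fails raises; >30% missingness on a
  variable warns, ≥50% refuses.

Diagnostics replace the usual plots numerically: median/IQR of imputed vs
observed values per variable, the death proportion among imputed outcomes,
and the regression slope (with p-value) of the per-cycle chain mean on
iteration number as a no-trend statistic.

## Pooling and survival

Rubin's rules: pooled estimate is the mean of the M estimates; total variance
T = W + (1 + 1/M)B; degrees of freedom use the Barnard–Rubin small-sample
adjustment with the complete-data residual df; CIs are t-based on the log-odds
scale and exponentiated. M = 1 is refused unless explicitly allowed.

Survival at 10 years is method-specific: Kaplan–Meier S(10) with Greenwood
variance for the complete-case route (ties handled deaths-before-censorings);
the Hájek-weighted alive proportion with a linearised variance for IPW; the
Rubin-pooled alive proportion across completed datasets for MICE. On a cohort
with nothing missing all three reduce to the same binomial proportion, which
the tests assert exactly.

## Pipeline conventions

- Tracing-resolved patients are folded into the known statuses before all
  four analyses, so "LTF" downstream always means never-found. Found-alive
  patients are censored at 10 years (their survival was confirmed);
  found-dead patients enter the Kaplan–Meier risk sets as events at their
  last visit, the only time anchor available for them.
- Per-model N bookkeeping is explicit: univariable complete-case N varies by
  predictor; the imputation models always use the full cohort; the
  delete-after-imputation models use exactly the outcome-observed rows
  (910 − 111 = 799 on a paper-shaped cohort).
- A failing method is recorded in the report's error map without aborting the
  other methods.
- Report serialization excludes wall-clock timings so regeneration from the
  same inputs is byte-identical.

## Problem sizes used in the test and acceptance runs

Monte-Carlo checks use the smallest sizes at which the tested property is
unambiguous: marginal-rate checks at the cohort's natural n = 910 with 3-SE
binomial bands; MAR/recency mechanism checks at n = 20,000–30,000; the
parameter-recovery experiments at 100 replicates × n = 10,000 (truth fit) and
50 replicates × n = 910 with M = 20 (full imputation pipeline); the MNAR bias
grid at n = 6,000 with three MNAR strengths. All randomness flows from
explicit integer seeds.

## Known limitations

- The MAR assumption is structural: when loss depends on the unobserved
  outcome itself, the imputation estimates are biased (monotonically in the
  MNAR strength — this is itself a tested property), and only the tracing
  route partially corrects it.
- The risk of death among the lost is treated as constant over follow-up by
  the imputation route; no time-to-event imputation is attempted.
- No Cox models, penalised logistic regression, or censoring-time IPW; the
  WHO stage enters as a single advanced/not-advanced indicator.
- The covariate-conditional IPW weights are exposed but not the pipeline
  default; the default reproduces the published outcome-stratum arithmetic.
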