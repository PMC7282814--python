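# Methods

`pacemeter` implements a measurement stack for the *pace of biological
aging*: a longitudinal biomarker composite, a DNA-methylation predictor of
it, scoring of methylation arrays with that predictor and with published
clock-style coefficient tables, Klemera–Doubal biological age, and the
validation-design estimators used to evaluate such measures. This note
records the models, the defaults and their rationale, the numerical
choices, and what the synthetic cohorts do and do not demonstrate.

## Pace of Aging

**Model.** For each biomarker *j* a random-intercept/random-slope growth
model is fitted to the repeated measures,

    y_ij(t) = (b0 + u0_i) + (b1 + u1_i) · t + e_ij(t),

with *t* the age centered at the first wave. A subject's rate of change is
the posterior (BLUP) slope `b1 + u1_i`, shrunk toward the cohort mean in
proportion to the informativeness of that subject's data; an independent
per-subject least-squares estimator is provided as an alternative
(`method="per_subject_ols"`). Subjects observed at fewer than two distinct
ages contribute no slope. A singular or non-converged mixed fit falls back
to per-subject least squares with a logged warning; the REML optimizer is
L-BFGS via statsmodels.

**Compositing.** Each slope column is multiplied by its orientation sign
(+1 if the biomarker rises with aging, −1 if it falls) and z-scored over
non-missing subjects. The composite is the unit-weighted mean of the
oriented z-scores over the biomarkers a subject has (subjects below a
minimum coverage — default half the panel — are dropped). The final pace is
the affine map

    pace_i = 1 + (c_i − mean(c)) / sd(c) · scale_sd,

which fixes the cohort mean at exactly 1 "year of physiological change per
calendar year". `scale_sd` defaults to 0.38, the dispersion conventionally
reported for this kind of birth-cohort composite; it is a display scale,
not an estimate, and is configurable. If every subject has an identical
composite the pace is defined as exactly 1 for all.

Unit weighting was chosen as the simplest scheme consistent with
"compositing slopes across biomarkers"; whether the historical composite
summed or averaged, and how it mapped to physiological units, is not
derivable here, so the affine-to-mean-1 map is a declared convention.

**Orientation fallback.** When decline directions are not supplied, signs
are taken from the loadings of the leading eigenvector of the slope
correlation matrix (the shared-pace axis), with the global sign fixed so a
majority of biomarkers come out positive. The *global* aging direction is
not identifiable from slopes alone — supplying known directions is always
preferable, and the fallback is only a convenience for exploratory data.

## Elastic-net pace predictor

Pace is regressed on the (optionally probe-filtered) beta matrix with an
elastic net; the mixing parameter defaults to 0.5 (an even L1/L2 blend, the
convention in this literature). Predictors are standardized inside the
fit and coefficients are exported back on the raw beta scale, so the
resulting weight table applies directly to beta matrices with no
preprocessing. Only nonzero coefficients are kept.

**Penalty strength.** The penalty path is tuned by seeded k-fold
cross-validation (default 10 folds). The default rule is the
*one-standard-error* rule — the largest penalty whose CV error is within
one SE of the minimum — rather than the CV minimum. Rationale: with a few
dozen true signal CpGs among thousands of null probes, the CV-minimum rule
admits roughly as many null probes as signal probes into the model, while
the 1-SE rule yields models in the 20–30-CpG range that are composed
mostly of true signal and match the sparsity of published pace predictors
(a 46-CpG model selected from hundreds of thousands of probes). The
CV-minimum rule remains available (`lambda_rule="cv_min"`).

**Bootstrap validity analysis.** `bootstrap_cv` repeats random train/test
splits (default 90/10 × 100): each repetition refits the elastic net on
the training split with a fresh fold seed, records the held-out
predicted-vs-measured correlation, and scores the full cohort so the
stability of the learned algorithm across resamples can be summarized as a
mean pairwise correlation. Splits are simple random and unstratified. The
in-sample correlation exceeds the mean held-out correlation by
construction of the optimism effect; the suite asserts the inequality, not
any particular pair of values.

## Scoring, imputation, calibration

A weight model scores a sample as `intercept + Σ_c w_c · β_c`. Missing
data policies at scoring time:

* `fail` — raise, listing the missing probes;
* `mean_impute` (default) — missing *cells* take the probe's cohort mean;
  probes absent from the matrix entirely have no cohort mean and raise;
* `reference_impute` — absent probes and missing cells take values from a
  supplied reference series.

A warning is emitted when more than 5% of a model's probes are imputed for
any sample. Chronological-age clocks that use the adult-age piecewise-log
calibration are supported via an invertible transform (`anti_log_linear`,
knot at 20 years by default) whose constants are read from `#calibration:`
header lines in the coefficient file, not hardcoded.

Batch residualization regresses the score on the given covariates
(categoricals dummy-coded) and adds the grand mean back, so scores keep
their units. Rank-deficient designs raise with the candidate collinear
columns named. Age acceleration is the residual from a simple regression
of a clock on chronological age.

## Klemera–Doubal biological age

Calibration regresses each biomarker on age in a reference sample of at
least 30 subjects, retaining intercept `q_j`, slope `k_j`, RMSE `s_j`, and
correlation `r_j`; biomarkers whose |age correlation| falls below 2/√n are
dropped with a warning. The uncorrected estimator is the precision-weighted
least-squares age

    BA_E = Σ_j (x_j − q_j) k_j / s_j² / Σ_j k_j² / s_j²,

the exact minimizer of Σ_j ((x_j − q_j − k_j t)/s_j)². The corrected
estimator treats chronological age as one more indicator with variance
`s2_BA`, estimated by method of moments as the variance of `BA_E − CA` in
the reference minus the noise-only dispersion
`((1 − r_char²)/r_char²) · (CA_max − CA_min)²/(12 m)`, where `r_char` is
the characteristic correlation of the m-biomarker battery. The corrected
estimate always lies between `BA_E` and chronological age; if `s2_BA`
comes out non-positive (as it should when biomarkers are purely
age-indexed), the corrected call falls back to `BA_E` with a warning. Both
estimators are exposed; the corrected form is the default, matching the
lineage of published implementations. Log-transforming skewed biomarkers
is the caller's responsibility.

## Validation estimators

All per-SD estimators standardize the score internally, making them
invariant to affine rescaling of the raw measure. CIs are Wald-type at
95%; a cluster column switches to cluster-robust standard errors.
Design-specific notes:

* `effect_size_r` — standardized OLS coefficient, equal to the Pearson
  correlation when no covariates are given.
* `change_analysis` — difference-score mode regresses (follow-up −
  baseline) on the score; residualized mode reads the score's
  standardized partial coefficient controlling baseline. Which mode is
  larger depends on baseline persistence; neither dominates universally.
* `poisson_irr` — Poisson regression with robust (HC1) errors by default,
  so binary incident outcomes can be expressed as rate ratios.
* `cox_hr` — lifelines Cox fit, plus Kaplan–Meier curves for the slow /
  average / fast strata cut at mean ± 1 SD of the score.
* `within_person_change` — the econometric within (subject-demeaning)
  transformation with degrees of freedom reduced by the number of
  subjects; slope rescaled per 5 years by default. This fixed-effects
  estimator is used for repeated-measures morbidity/score-drift designs
  in place of generalized estimating equations: the GEE working
  correlation used historically is not documented, whereas the
  fixed-effects estimator is transparent and removes all stable
  between-person confounding.
* `group_contrast` — Cohen's d vs the reference category, with the CI from
  a (cluster-aware) regression of the pooled-SD-scaled score on the group
  indicator, plus a linear-trend coefficient over ordered categories.
* `trial_interaction_model` — mixed-effects growth model of the outcome on
  time × condition × standardized baseline score with a random intercept
  (optional random slope; a singular random-slope fit is retried with the
  intercept only). Reports the 3-way coefficient, per-arm
  slope-per-SD coefficients, and model-implied slopes at baseline ± 1 SD.

The null-calibration suite draws effect-free datasets and checks that each
estimator's 95% CI covers its null 93–97% of the time over 1000
repetitions — the binomial band around nominal coverage.

## Synthetic cohorts

The generators produce every input the pipeline consumes; all are pure
functions of their arguments and an integer seed (per-generator stream
tags are mixed into the seed so equal integers across generators never
alias bit streams).

* **Longitudinal panel** — default 500 subjects, 18 biomarkers, waves at
  ages 26/32/38. Latent pace is Gaussian with mean 1 and SD 0.38. Each
  biomarker's true slope is `base_rate_j + loading · (pace_i − 1) +
  idiosyncratic`, with loading and idiosyncratic variance set so the
  cross-biomarker slope correlation hits the configured target (default
  0.6) and the total slope SD is 0.1/year against visit noise of SD 0.5.
  15% of subject–biomarker series lose one random wave; this mild
  unbalance is what gives BLUP shrinkage its advantage over per-subject
  least squares in the recovery checks. Orientation alternates rising and
  falling biomarkers.
* **Methylation** — logit-normal betas (guaranteeing values in (0,1));
  signal CpGs shift their logit mean linearly with pace. The default
  effect size 0.45 per pace unit with logit noise SD 0.5 yields a
  univariate beta-pace correlation near 0.3 per signal CpG. A separate
  `layout_seed` fixes the signal-CpG identities and means so independent
  cohorts can be drawn from one population (used by the large-sample
  oracle check).
* **Cross-section** — uniform ages, linear score-age gradient plus
  Gaussian noise; `age_slope_for_r` converts a target population
  correlation (e.g. 0.11 over ages 28–95 with score SD 0.07) into a slope.
* **Survival** — exponential event times with hazard ∝ exp(log-HR · z),
  censoring uniform on (0, c) with c solved so the expected event
  fraction matches the target (the same closed form serves as the test
  oracle).
* **Trial** — 2:1 allocation, visits at months 0/12/24, control-arm
  biological-age slope 0.71 years/year rising 0.22 per SD of baseline
  score, treatment-arm slope 0.11 with the score dependence shifted by the
  planted interaction (default −0.30), visit noise 1 year. These defaults
  echo a 220-person caloric-restriction trial.
* **KDM reference** — 8 biomarkers linear in a latent biological age
  `CA + N(0, 5²)`; setting `ba_sd=0` gives purely age-indexed biomarkers
  for calibration-recovery tests.

**What passing tests do not show.** The generators have no probe-type or
batch structure beyond an optional categorical shift, no cell-composition
signal, no twin-pair correlation, Gaussian biomarker noise, and linear
trajectories. Recovery and calibration results on them verify the
estimators' internal correctness, not performance on real arrays; cohort
effect sizes reported in the aging literature require the restricted
cohort data and are deliberately not reproduced here.

## Problem sizes and runtime

The benchmark suite (`pacemeter.benchmarks`, driven by
`scripts/acceptance.py` and the acceptance tests) uses: the default
500-subject panel; a 400 × 2000-CpG training cohort for selection
recovery; a 500 × 1000-CpG cohort with 20 repetitions of 90/10 splits plus
a 5000-sample training / 10,000-sample testing oracle for the bootstrap
check; 100 repetitions for planted-effect coverage; and 1000 repetitions
for null calibration. These sizes keep the full recomputation within a few
minutes on one CPU while leaving Monte-Carlo error well inside the asserted
tolerances.

## Known limitations

* The mixed-model growth fit is per-biomarker; a joint multivariate model
  of all 18 biomarkers would pool information across markers but is far
  heavier and is not attempted.
* `s2_BA` uses the method-of-moments expression above; other recipes exist
  and give somewhat different corrected estimates. Both estimator forms
  are exposed for that reason.
* The data-driven orientation fallback cannot identify the global aging
  direction (sign flip of the whole composite).
* Scoring treats betas as given; no normalization-pipeline sensitivity is
  modeled.
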