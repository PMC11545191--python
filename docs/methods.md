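# Methods

This package implements a point-based "heart age" calculator together with
the analysis chain that relates three atherogenic lipid indices to an
elevated heart age: risk categorization, ROC/Youden cut-off discovery, and
age-stratified logistic odds ratios.  Because the population it emulates is
a private occupational-health cohort, everything is exercised on a synthetic
cohort generator calibrated to the published sex-stratified marginals.  This
note records the model, the parameters that matter, the numerical choices,
and the limits of what the synthetic validation shows.

## The heart-age score and ALLY

Six risk factors — total cholesterol, HDL-c, fasting glucose, smoking, BMI,
and blood pressure — each contribute an integer number of points from a
sex-specific banded chart (shipped as the versioned asset
`heartage/assets/points_table.yaml`).  The summed points shift the
chronological age (CA):

    HA = CA + clamp(Σ points, −20, +19)

The clamped shift is the ALLY statistic ("avoidable lost life years" heart
age, HA − CA), and ALLY ≥ 17 years is classified as *high*.  The calculator
is valid for ages 18–80.

Conventions adopted where the printed chart is ambiguous:

* **Half-open bands.**  Printed integer bands like `130–145 / 146–160`
  become `[130, 146) / [146, 161)` so a continuous laboratory value can
  never fall between bands; the printed gap `200–239 / >240` becomes
  `[200, 240) / [240, ∞)`.
* **Women's HDL ladder.**  The last printed row `<75 → −5` contradicts the
  preceding `71–75 → −4` row and the men's column; it is encoded as the
  `>75` band, completing an ascending ladder.
* **Discordant blood pressures.**  Systolic and diastolic are banded
  independently against their own thresholds and the *higher-points* band
  wins, the usual convention in categorical risk scores.
* **Clamp asymmetry.**  The per-factor maxima sum to +20 raw points but the
  stated ceiling on the age shift is +19; both the raw sum and the clamped
  shift are reported so either convention can be audited.
* **Treatment overrides.**  Being under treatment for glucose or blood
  pressure yields that factor's maximum points regardless of the measured
  value.  Lipid-lowering treatment is not recorded and gets no override.
* **Inclusive cut-offs.**  ALLY = 17.0 is *high*; index ratios exactly at a
  category boundary (TC/HDL 4.5 and 7 in women, 5 and 9 in men; LDL/HDL and
  TG/HDL at 3) fall in the *higher* category.

A structural consequence worth stating explicitly: the five non-smoking
factors can contribute at most 2+2+5+3+3 = 15 points, so **only smokers can
reach the 17-year high-ALLY cut-off**.  In any regression of high ALLY on
covariates that include smoking, the smoker term is therefore
quasi-separated by construction whenever the outcome was produced by this
chart, and the maximum-likelihood fit correctly diverges.  The stratified
regression is consequently run without the smoker covariate on table-scored
outcomes, and the regression machinery itself is validated against injected
known odds ratios instead (below).

## Lipids and atherogenic indices

Missing LDL-c is derived by the Friedewald relation `LDL = TC − HDL − TG/5`
(mg/dL throughout), trusted only when TG ≤ 400 mg/dL and the result is
positive; otherwise the row keeps its raw value, flagged unusable, and is
excluded from LDL-based analyses only — never from the cohort.  The three
indices are plain ratios: TC/HDL (three categories, sex-specific cut-offs),
LDL/HDL and TG/HDL (binary at 3).

## Synthetic cohort generator

The generator emulates a Spanish working population aged 20–69 at its
published size (83,282 men, 56,352 women by default) using only published
marginals: per-sex means/SDs for height, BMI, waist, SBP, DBP, TC, HDL-c and
glucose; age-band weights; and prevalences for smoking, physical activity,
Mediterranean-diet adherence, alcohol use, social class and education.

* **Marginals.**  Continuous fields are truncated normals on physiological
  bounds (e.g. SBP ∈ [80, 250] mmHg, HDL ≥ 10 mg/dL).  The pre-truncation
  (μ, σ) are solved numerically so the *truncated* distribution has exactly
  the configured mean/SD.  Triglycerides are log-normal, moment-matched to
  the configured mean/SD, because the male TG SD is nearly equal to its mean
  — impossible for a normal on the positive half-line.  BMI is parametrized
  directly (it is both a published marginal and the quantity the score
  consumes) and weight is derived as BMI × height²; weight therefore matches
  its population mean closely but its SD is implied, not configured.
* **Dependence.**  Only marginals are published, so the joint structure is
  invented and deliberately minimal: one shared standard-normal latent
  "metabolic" factor Z with loading λ (`latent_effect`, default 0.6) enters
  each loaded field through a Gaussian copula — the mixed normal
  ±λZ + √(1−λ²)ε is pushed through the truncated-normal inverse CDF.  TC,
  TG, glucose, BMI, SBP, DBP load positively, HDL negatively; every loaded
  pair then has rank-correlation ≈ ±λ² (≈ 0.36 at the default), in the range
  reported for metabolic risk-factor clustering.  Lifestyle covariates and
  age are independent of Z.
* **Determinism.**  All draws descend from one seed through named child
  streams (men, women, injected outcome), so a (config, seed) pair
  reproduces a cohort bit-for-bit.
* **Known-effect injection.**  For estimator validation,
  `inject_known_effect` adds an outcome drawn from
  `logit P = logit(p₀) + log(OR)·x` on a chosen 0/1 covariate (default
  smoking, baseline probability 0.25), giving the regression stage a ground
  truth to recover.
* **Treatment flags** (`bp_treated`, `glucose_treated`) default to
  prevalence 0 because the source population reports none; they are config
  fields, not constants.

What the generator does **not** emulate: any age trend in the risk factors
(each sex draws one set of moments for all ages, so ALLY is flat in age and
index means do not rise across age bands); the real joint distribution
beyond one latent factor; measurement error or digit preference; and the
published prevalence of high ALLY.  On that last point: with the printed
chart and published marginals, high ALLY is intrinsically rare (≈0.5% of
men, ≈0.15% of women at λ = 0.6) because ≥ 17 of a maximum 20 raw points
requires the worst band of nearly every factor simultaneously.  The
published prevalences (≈12–86% by index category) are therefore not
reproducible from the printed ingredients, and no attempt is made to match
published AUCs or ORs; the synthetic analyses validate *machinery and
qualitative structure* (categories order mean ALLY correctly, AUC > 0.5 and
growing with λ), not published effect sizes.

## Statistics

* **ROC.**  Higher score predicts the positive class.  Operating points sit
  at midpoints between consecutive distinct scores plus ∓∞ sentinels; the
  AUC is the trapezoidal area, which equals the tie-corrected rank
  statistic (concordant + ½ ties)/(n₁n₀) — the suite checks the two routes
  agree to 1e−12.  The 95% CI uses the DeLong structural-components
  variance (cross-checked against R's pROC); a seeded bootstrap is
  available behind `ci_method="bootstrap"`.  The reported cut-off maximizes
  Youden's J = sensitivity + specificity − 1, ties broken toward the
  smaller threshold.
* **Logistic regression.**  Newton/IRLS from a zero start; convergence when
  the largest score component falls below 1e−8, at most 50 iterations.
  Diverging coefficients (|β| > 30) or a singular information matrix raise
  a separation diagnostic rather than returning a silent result.  ORs are
  exp(β) with Wald 95% CIs; categorical covariates are dummy-coded against
  declared reference levels (women, class I, university, non-smoker,
  active, diet-adherent, non-drinker, low/normal index).
* **Hosmer–Lemeshow.**  Deciles of fitted risk (g = 10 by default),
  statistic Σ (O−E)²/(E(1−E/n_g)), df = g − 2; degenerate groups are merged
  into a neighbour with a logged warning; g ≤ 2 is an error.
* **Stratified analysis.**  The same binary logistic model fit
  independently in half-open decade age bands 20–70; empty, single-class or
  separated strata are skipped with an explicit warning.  (A two-level
  "multinomial" outcome is mathematically identical to binary logistic.)
* **Bivariate tables.**  Welch's t for group means; chi-square (continuity
  correction optional, off by default) with Fisher's exact fallback for
  2×2 tables containing an expected cell below 5.  Significance level 0.05
  throughout; no multiplicity correction is applied.

## Problem sizes and validation design

The tests and the acceptance script choose sizes that make each check
informative at interactive cost: marginal calibration at n = 20,000 per sex
(1% mean tolerance, ≫ 3 Monte-Carlo SEs); AUC oracle equivalence on 100
random datasets of n ≤ 500; OR recovery over 100 replicates of n = 5,000
per target OR ∈ {0.5, 1, 2} (mean within 10%, CI coverage 95 ± 3%);
Hosmer–Lemeshow null calibration over 200 replicates of n = 1,000
(rejection rate in [0.02, 0.09]); and the full-size default cohort
(139,634) for the end-to-end pipeline.  The analysis scripts under
`analysis/` narrate the same pipeline at full size.

## Known limitations

* The dependence structure is a single latent factor; real lipid–pressure–
  glycaemia covariance is richer, and none of the lifestyle covariates are
  correlated with the metabolic factor or with each other.
* Without an age trend in the generator, the age-band table is flat and the
  stratified regression can only be validated for homogeneity and injected
  effects, not for the published age gradient.
* The Table-shaped OR report on table-scored outcomes omits the smoker term
  (structural separation, above) and may still skip strata where a rare
  index category is single-class at realistic prevalence.
* Friedewald-derived LDL inherits that formula's known bias at high TG even
  below the 400 mg/dL bound.
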