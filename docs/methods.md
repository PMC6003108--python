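# Methods

This note documents the statistical models, conventions and design
choices behind `rmragree`, and what the simulation-based tests do and
do not establish.

## Cohort model and classification conventions

A subject is (gender, integer age in years, weight in kg, height in m,
optional education level, optional measured RMR in kcal/day). Heights
are metres everywhere in the data model; equations whose coefficients
expect centimetres convert internally, so a unit error would have to be
introduced in exactly one place (the equation config's `height_unit`).

**BMI classes** follow WHO cutoffs, lower-inclusive:
BMI < 18.5 underweight (code 0), [18.5, 25) normal (1), [25, 30)
overweight (2), [30, 35) obesity I (3), [35, 40) obesity II (4),
≥ 40 obesity III (5). A BMI of exactly 25.0 is overweight. Underweight
subjects are kept in the data model but carry an exclusion flag that
every statistics stage honours: adult cohorts of this kind contain too
few underweight subjects for them to support any of the per-class
estimates, and codes 1–5 are what the power-law model is defined on.

**Age groups** are 10–18, 19–30, 31–45, 46–60 and 61+ (codes 1–5).
The groups are closed on integers and partition [10, 120] without gap
or overlap; ages below 10 are outside the supported range (the
equations' paediatric forms are not modelled). Where the literature
names groups like "19–30" and "30–45" without stating closure, the
integerized right-closed convention above was fixed once and used
everywhere.

## The prediction-equation library

Nine equations are configured, grouped by the covariates they use:

1. weight, height, age, gender — Harris–Benedict (1919), the
   Roza–Shizgal revision, Mifflin–St Jeor;
2. weight, height, age group, gender — FAO/WHO/UNU weight+height;
3. weight, age group, gender — FAO/WHO/UNU weight-only, Schofield;
4. weight, gender — Owen, abbreviated Harris–Benedict
   (24.0 / 22.8 kcal/kg for men / women);
5. BMI, age, gender — a placeholder slot (see below).

Coefficients live in a shipped YAML file rather than code: published
variants of these equations differ in minor digits, and a user should
be able to swap a variant in without touching the library. Validation
enforces that, per gender, age brackets cover 10–120 with no interior
overlap and no gap; adjacent brackets may share an endpoint, and
dispatch gives the shared age to the *lower* bracket (age 18 uses the
10–18 row, age 30 the 18–30 row) as a deterministic tie-break. The
10–18 rows are the junior Schofield / FAO-WHO-UNU forms, applied to the
adolescent subgroup.

The category-5 slot ships as a placeholder with no coefficient rows:
the BMI-based equation it stands for has no coefficient table in the
sources bundled here, and inventing one would silently misrepresent it.
`predict_all` skips placeholder slots with a warning; filling in `rows`
activates the slot.

Predictions are pure functions of (subject, spec): re-loading the
config and re-predicting is bit-identical.

## Agreement statistics

For paired series RMRm (measured) and RMRe (estimated), per equation:

* mean bias = mean(RMRe − RMRm); positive values are overestimates;
* 95% CI on the mean bias: mean ± t₀.₉₇₅,ₙ₋₁ · sd/√n. A t rather than
  z interval: at n ≈ 380 they are indistinguishable, and t remains
  correct on the small fixtures the tests use. A percentile bootstrap
  (10⁴ resamples) serves as an independent oracle in the tests;
* absolute bias = |mean(RMRm) − mean(RMRe)|, which equals |mean bias|
  when computed on the same subject set;
* accuracy (percentage deviation) = absolute bias × 100 / mean, with
  both denominators (measured and estimated) reported;
* adequacy: *strictly* below the 10% threshold in both directions;
* n_within_10: the count of subjects whose individual deviation
  |RMRe − RMRm| × 100 / RMRm is ≤ 10% (boundary counts).

Note the asymmetry, which is deliberate: the aggregate adequacy rule is
strict (`< 10`), the per-subject count is inclusive (`≤ 10`).

Display rounding follows the field's reporting style — kcal quantities
to integers, percentages to one decimal — while all internal
computation is at full precision. Because displayed means are rounded,
a bias column recomputed from displayed means can differ from the
displayed bias by a few kcal; the package never does that internally.

## Bias-factor regression

Per-subject absolute bias |RMRe − RMRm| is strictly positive and
right-skewed. It is normalised by a Box-Cox power transform whose λ is
chosen by profile maximum likelihood on the grid [−1, 1.5] in steps of
0.01 (values near 0.34–0.41 — between log x and √x — are typical for
these biases). The grid log-likelihood is evaluated vectorised and
matches `scipy.stats.boxcox_llf` exactly on the grid points; the grid
keeps λ reproducible and cheap at the cost of 0.01 resolution, which is
far below the sampling noise of λ̂ at these sample sizes.

The transformed bias is regressed on three categorical main effects —
gender, BMI class, age group; no interactions — via OLS with type-II
whole-factor F tests. Backward elimination removes one factor per step,
the largest p first (ties broken in the fixed order gender → BMI class
→ age group), until every remaining factor has p ≤ α (default 0.05).
With α = 1 nothing is eliminated; with α = 0 everything is. Factor
levels with fewer than 2 observations are collapsed into the nearest
level (by level order) with a warning; a factor reduced to a single
level is dropped up front. Reference levels are the first level of each
factor (female, normal weight, 10–18); this affects dummy coefficients
only, never the F tests or the per-level effect profiles.

Effect profiles — per-level means of the transformed bias — are the
input to a main-effects plot; under the generator's defaults the
abbreviated Harris–Benedict bias profile rises monotonically across BMI
classes, and simulations with a single injected factor effect recover
exactly that factor.

## Cross-tabulations

Pearson chi-square tests of independence (no continuity correction —
the primary tables are r×5, not 2×2) between BMI classes 1–5 and
gender, age group or education, excluding underweight subjects and,
for education, the `unknown` level. Standardized residuals are
(O − E)/√E, matching the |residual| > 2 rule of thumb for flagging
over-/under-represented cells; adjusted residuals
(O − E)/√(E(1 − p_row)(1 − p_col)) are available as an option but are
not the default, since the flagging threshold is calibrated to the
unadjusted form. The chi-square statistic equals the sum of squared
unadjusted residuals, and its p-value is checked in the tests against a
label-shuffling permutation oracle (10⁴ shuffles).

## The BMI-class power law

The response is mean measured RMR per kg body weight (kcal/kg/day); the
regressor is the **integer class code 1–5, not raw BMI**. This is the
canonical form: with class means as data, OLS of log10(mean) on
log10(code) attains R² near 99%, which an individual-level or raw-BMI
fit cannot (within-class dispersion caps it far lower). Both
non-canonical variants — per-subject fits, and raw BMI as regressor —
are provided, clearly labelled, for sensitivity analysis.

Per-class means carry t-based 95% CIs; a class with one subject or zero
variance gets a degenerate (zero-width) interval, and empty classes are
omitted with a warning. The fitted model back-transforms to
`c = 10^intercept` and exponent `b`, predicting
`RMR (kcal/day) = c · k^b · weight`; class 0 is rejected (outside the
fitted domain). Whenever b < 0 the predicted per-kg RMR is strictly
decreasing in class code.

## The synthetic-cohort generator

The generator emulates the *population structure the analysis assumes*,
not any particular dataset:

* counts 105 men / 278 women;
* per-gender truncated normals — men: age 37.5 ± 15 y on [10, 77],
  weight 100.1 ± 23.1 kg on [59, 177], height 1.76 ± 0.08 m on
  [1.44, 1.98]; women: age 37.5 ± 14 y on [12, 76], weight
  79.7 ± 20 kg on [42.7, 166], height 1.63 ± 0.06 m on [1.48, 1.86];
* weight and height coupled by a Gaussian copula with ρ = 0.4. Only
  marginals are published for such cohorts; ρ = 0.4 is a realistic
  adult within-gender value and gives BMI a spread covering at least
  four of the five analysis classes;
* measured RMR generated from the class-code power law
  RMRm = weight · c_g · k^{b_g} · 10^ε with ε ~ N(0, 0.04) in log10
  units (≈ 9.6% CV). Defaults: men c = 25.41, b = −0.2115; women
  c = 21.09, b = −0.1786. The noise level is a tuning default chosen so
  that simulated per-equation accuracies land in the 2–25% range seen
  in real method-comparison studies, not a measured quantity. The few
  by-chance underweight subjects use k = 1 (the model is defined on
  codes 1–5);
* education is sampled with base probabilities (0.20, 0.45, 0.35) for
  primary/secondary/tertiary and a 1.5× odds tilt on tertiary among
  normal-weight subjects — direction as observed in population studies,
  magnitude synthetic, present so the education cross-tab has a real
  dependence to find.

All randomness flows from one integer seed; the same (config, seed) is
bit-reproducible.

**What passing tests show — and don't.** Because RMRm is generated from
the class-code power law, end-to-end recovery tests certify the
estimation machinery (classification → class means → log-log OLS), not
the biological truth of the power-law form. The generator draws age
independently of weight/height, has no within-class BMI–RMR trend, no
seasonal or device effects, and no missing strata by construction
(particular gender × age × class cells may still be empty by chance).
Results on real cohorts depend on how well that structure holds.

## Numerical and scale choices

* Box-Cox grid [−1, 1.5] step 0.01; degenerate (constant) samples and
  non-positive values are errors — offsetting is the caller's choice.
* Agreement requires n ≥ 3 pairs; the power-law fit n ≥ 3 points;
  Box-Cox n ≥ 10.
* Simulation sizes: the exponent-recovery check averages 100 generator
  seeds at n = 383 (tests) and 50 seeds in the acceptance script; the
  type-I calibration uses 1000 null replicates at n = 380; permutation
  and bootstrap oracles use 10⁴ resamples. These sizes put Monte-Carlo
  error well below the assertion tolerances.
* The acceptance script derives per-replicate seeds from `--seed` via
  `numpy.random.SeedSequence.spawn`, keeping them below 2³¹.

## Known limitations

* The category-5 (BMI-based) equation slot is a placeholder; agreement
  results for it can only be compared at the summary level.
* Bland–Altman limits of agreement are intentionally out of scope; the
  agreement statistics here are means-based.
* No body-composition covariates (fat-free mass / fat mass), no
  paediatric (< 10 y) support, no total-energy-expenditure or
  activity-factor modelling.
* The backward-elimination p-values are not corrected for selection;
  the type-I simulation shows per-factor retention near α, but
  post-selection inference caveats apply as in any stepwise procedure.
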