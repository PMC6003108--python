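# rmragree

Agreement analysis between resting-metabolic-rate (RMR) prediction
equations and indirect-calorimetry measurements, with a BMI-class
power-law RMR model and a seeded synthetic-cohort generator.

## The problem

Resting metabolic rate — the energy a person expends at rest, in
kcal/day — is measured with indirect calorimetry, but in practice it is
usually *predicted* from anthropometrics with published linear
equations (Harris–Benedict and its revisions, Mifflin–St Jeor, Owen,
Schofield, FAO/WHO/UNU). How well do those equations agree with a
calorimeter on a given population, and what drives their errors?

`rmragree` is aimed at nutrition and epidemiology researchers who want
this method-comparison analysis as tested, reusable code:

* **Agreement statistics.** For each equation, the mean bias (mean of
  estimated − measured, positive = overestimation) with a 95% t
  confidence interval, the absolute bias |mean(RMRm) − mean(RMRe)|, and
  the percentage accuracy in both directions,
  `accuracy = absolute bias × 100 / mean`, with deviations below 10%
  deemed adequate.
* **Bias-factor regression.** Per-subject absolute bias is normalised
  with a Box-Cox transformation (λ by profile maximum likelihood on a
  grid) and regressed on gender, WHO BMI class and age group, with
  whole-factor F tests and backward elimination at α = 0.05.
* **Cross-tabulations.** Pearson chi-square tests of independence
  between BMI classes and gender / age group / education, with
  standardized residuals (O − E)/√E and a |residual| > 2 flagging rule.
* **BMI-class power law.** Mean measured RMR per kg body weight
  declines with BMI class `k` ∈ {1..5} (normal weight → obesity III) as

      RMR (kcal/kg/day) = c · k^b,
      log10(RMR) = intercept + b · log10(k),

  fitted by OLS on the five class means. This is the basis for a new
  class-indexed prediction: `RMR (kcal/day) = c · k^b · weight`.
* **Synthetic cohorts.** Raw subject-level data for this kind of study
  are typically not deposited, so the generator draws cohorts (105 men,
  278 women by default) from per-gender truncated-normal
  anthropometrics with correlated weight/height, and generates measured
  RMR from gender-specific power laws (men c = 25.41, b = −0.2115;
  women c = 21.09, b = −0.1786) with multiplicative lognormal noise —
  so every pipeline stage is testable end to end with a known truth.

## Worked example

```python
import warnings
import rmragree as rr
from rmragree.agreement import agreement_table, format_agreement_table
from rmragree.bmi_fit import fit_power_law_by_gender, fit_report
from rmragree.equations import default_equations, predict_all

cohort = rr.generate_cohort(rr.default_config(seed=42))
specs = default_equations()
with warnings.catch_warnings():
    warnings.simplefilter("ignore")   # placeholder-equation notice
    matrix = predict_all(cohort, specs)
print(format_agreement_table(agreement_table(matrix, specs=specs)))
print(fit_report(fit_power_law_by_gender(cohort)).round(4).to_string())
```

prints

```
             n   min   max  mean   sd  mean_bias  bias_ci_low  bias_ci_high  abs_bias  accuracy_vs_m_pct  accuracy_vs_e_pct  n_within_10 adequate
equation
RMRm       379   879  3270  1644  402       <NA>         <NA>          <NA>      <NA>                NaN                NaN          NaN      NaN
H-B        379  1045  2949  1722  341         78           59            97        78                4.8                4.6        204.0     True
H-B_Rev    379  1034  2903  1707  338         63           45            82        63                3.9                3.7        218.0     True
Mifflin    379   895  2578  1626  304        -18          -37             1        18                1.1                1.1        238.0     True
F-W-U_1    379  1053  3042  1741  351         97           77           116        97                5.9                5.6        199.0     True
F-W-U_2    379  1047  3039  1751  352        107           86           127       107                6.5                6.1        183.0     True
Schofield  379  1048  3014  1732  356         88           67           109        88                5.3                5.1        188.0     True
Owen       379  1103  2452  1540  291       -104         -123           -84       104                6.3                6.7        205.0     True
H-B_Abbr   379   979  3701  2052  522        408          380           436       408               24.8               19.9       67.0    False

        coefficient  exponent  intercept_log10   r2_pct  n_points
scope
both        21.9174   -0.1672           1.3408  98.1901         5
male        25.8113   -0.2178           1.4118  97.3277         5
female      21.2258   -0.1813           1.3269  97.8656         5
```

Reading this: of the 383 simulated subjects, 379 enter the statistics
(underweight subjects are excluded). Equations that use weight, height,
age and gender sit within ~5% of the calorimeter values (adequate),
while the flat 24/22.8 kcal/kg abbreviated Harris–Benedict rule
overshoots an obesity-skewed cohort by ~25% — exactly the pattern that
motivates a BMI-aware equation. The class-means power-law fits recover
the generating exponents (−0.2115 male, −0.1786 female) to ~0.005 at
this seed, with R² in the 97–98% range.

The same pipeline is scriptable from the shell:

```sh
rmragree all --seed 42 --out report/        # simulate + every table
rmragree agree --input cohort.csv           # your own cohort CSV
```

Cohort CSVs use the header
`id,gender,age,weight_kg,height_m,education,rmr_kcal_day` (heights in
metres). Equation coefficients live in an editable YAML config
(`src/rmragree/data/equations.yaml`); the bundled category-5 BMI-based
slot ships as a placeholder to be filled with coefficients of your
choice.

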