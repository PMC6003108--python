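# Default RMR prediction-equation coefficient tables (kcal/day).
#
# Each block: name, covariate category (1-5), required covariates, the
# unit the height coefficient expects (cm or m), and one coefficient row
# per (gender, age bracket).  Rows are linear:
#   RMR = intercept + weight*W[kg] + height*H + age*A[y] + bmi*BMI
# Brackets may share an endpoint; dispatch gives the lower bracket the
# shared age (age 18 -> 10-18, age 30 -> 18-30).
#
# Sources: Harris-Benedict 1919 originals; Roza & Shizgal 1984 revision;
# abbreviated per-kg Harris-Benedict factors; Mifflin-St Jeor 1990
# (gender offset folded into the intercepts); Owen 1986/1987 weight-only;
# Schofield 1985 weight-only tables; FAO/WHO/UNU 1985 weight+height and
# weight-only tables.  The Harrington slot (BMI, age, gender) ships as a
# placeholder: no published coefficient table is bundled, fill in `rows`
# to activate it.

- name: H-B
  category: 1
  covariates: [weight, height, age, gender]
  height_unit: cm
  rows:
    - {gender: male,   age_min: 10, age_max: 120, intercept: 66.4730,  weight: 13.7516, height: 5.0033, age: -6.7550}
    - {gender: female, age_min: 10, age_max: 120, intercept: 655.0955, weight: 9.5634,  height: 1.8496, age: -4.6756}

- name: H-B_Rev
  category: 1
  covariates: [weight, height, age, gender]
  height_unit: cm
  rows:
    - {gender: male,   age_min: 10, age_max: 120, intercept: 88.362,  weight: 13.397, height: 4.799, age: -5.677}
    - {gender: female, age_min: 10, age_max: 120, intercept: 447.593, weight: 9.247,  height: 3.098, age: -4.330}

- name: Mifflin
  category: 1
  covariates: [weight, height, age, gender]
  height_unit: cm
  rows:
    - {gender: male,   age_min: 10, age_max: 120, intercept: 5.0,    weight: 9.99, height: 6.25, age: -4.92}
    - {gender: female, age_min: 10, age_max: 120, intercept: -161.0, weight: 9.99, height: 6.25, age: -4.92}

- name: F-W-U_1
  category: 2
  covariates: [weight, height, age_group, gender]
  height_unit: m
  rows:
    - {gender: male,   age_min: 10, age_max: 18,  intercept: 572.0,   weight: 16.6, height: 77.0}
    - {gender: male,   age_min: 18, age_max: 30,  intercept: 717.0,   weight: 15.4, height: -27.0}
    - {gender: male,   age_min: 30, age_max: 60,  intercept: 901.0,   weight: 11.3, height: 16.0}
    - {gender: male,   age_min: 60, age_max: 120, intercept: -1071.0, weight: 8.8,  height: 1128.0}
    - {gender: female, age_min: 10, age_max: 18,  intercept: 217.0,   weight: 7.4,  height: 482.0}
    - {gender: female, age_min: 18, age_max: 30,  intercept: 35.0,    weight: 13.3, height: 334.0}
    - {gender: female, age_min: 30, age_max: 60,  intercept: 865.0,   weight: 8.7,  height: -25.0}
    - {gender: female, age_min: 60, age_max: 120, intercept: -302.0,  weight: 9.2,  height: 637.0}

- name: F-W-U_2
  category: 3
  covariates: [weight, age_group, gender]
  rows:
    - {gender: male,   age_min: 10, age_max: 18,  intercept: 651.0, weight: 17.5}
    - {gender: male,   age_min: 18, age_max: 30,  intercept: 679.0, weight: 15.3}
    - {gender: male,   age_min: 30, age_max: 60,  intercept: 879.0, weight: 11.6}
    - {gender: male,   age_min: 60, age_max: 120, intercept: 487.0, weight: 13.5}
    - {gender: female, age_min: 10, age_max: 18,  intercept: 746.0, weight: 12.2}
    - {gender: female, age_min: 18, age_max: 30,  intercept: 496.0, weight: 14.7}
    - {gender: female, age_min: 30, age_max: 60,  intercept: 829.0, weight: 8.7}
    - {gender: female, age_min: 60, age_max: 120, intercept: 596.0, weight: 10.5}

- name: Schofield
  category: 3
  covariates: [weight, age_group, gender]
  rows:
    - {gender: male,   age_min: 10, age_max: 18,  intercept: 658.2, weight: 17.686}
    - {gender: male,   age_min: 18, age_max: 30,  intercept: 692.2, weight: 15.057}
    - {gender: male,   age_min: 30, age_max: 60,  intercept: 873.1, weight: 11.472}
    - {gender: male,   age_min: 60, age_max: 120, intercept: 587.7, weight: 11.711}
    - {gender: female, age_min: 10, age_max: 18,  intercept: 692.6, weight: 13.384}
    - {gender: female, age_min: 18, age_max: 30,  intercept: 486.6, weight: 14.818}
    - {gender: female, age_min: 30, age_max: 60,  intercept: 845.6, weight: 8.126}
    - {gender: female, age_min: 60, age_max: 120, intercept: 658.5, weight: 9.082}

- name: Owen
  category: 4
  covariates: [weight, gender]
  rows:
    - {gender: male,   age_min: 10, age_max: 120, intercept: 879.0, weight: 10.2}
    - {gender: female, age_min: 10, age_max: 120, intercept: 795.0, weight: 7.18}

- name: H-B_Abbr
  category: 4
  covariates: [weight, gender]
  rows:
    - {gender: male,   age_min: 10, age_max: 120, intercept: 0.0, weight: 24.0}
    - {gender: female, age_min: 10, age_max: 120, intercept: 0.0, weight: 22.8}

- name: Harrington
  category: 5
  covariates: [bmi, age, gender]
  placeholder: true
  rows: []
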