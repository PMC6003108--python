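"""Synthetic anthropometric cohorts with a known RMR generating model.

The raw study data behind this kind of agreement analysis are rarely
deposited, so every pipeline stage is exercised on simulated cohorts
whose statistical structure matches the population the analysis assumes:

* 105 men and 278 women;
* per-gender truncated-normal marginals for age, weight and height
  (men: age 37.5 ± 15 y in 10-77, weight 100.1 ± 23.1 kg in 59-177,
  height 1.76 ± 0.08 m in 1.44-1.98; women: age 37.5 ± 14 y in 12-76,
  weight 79.7 ± 20 kg in 42.7-166, height 1.63 ± 0.06 m in 1.48-1.86);
* weight and height positively correlated within gender through a
  Gaussian copula (default rho = 0.4) so that BMI gets realistic spread;
* measured RMR generated from the gender-specific BMI-class power law

      RMR_m = weight * c_g * k^{b_g} * 10^eps,  eps ~ N(0, sigma)

  with k the BMI class code (clamped to >= 1 for the rare by-chance
  underweight subject), defaults c/b of 25.41/-0.2115 for men and
  21.09/-0.1786 for women, and multiplicative lognormal noise of
  sigma = 0.04 log10 units (~9.6% CV);
* an education level whose tertiary share is enriched among
  normal-weight subjects (odds multiplier 1.5) so that the BMI-education
  cross-tabulation has a detectable dependence of realistic direction.

All randomness flows from a single integer seed; the same seed yields a
bit-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

import numpy as np
from scipy import stats

from .cohort import Education, Gender, Subject, classify_bmi


class GeneratorConfigError(ValueError):
    pass


@dataclass(frozen=True)
class TruncNormalSpec:
    """Truncated-normal marginal: mean/sd with hard bounds."""

    mean: float
    sd: float
    low: float
    high: float

    def __post_init__(self):
        if not self.low < self.high:
            raise GeneratorConfigError(
                f"truncation bounds must satisfy low < high, got "
                f"({self.low}, {self.high})"
            )
        if self.sd <= 0:
            raise GeneratorConfigError("sd must be positive")

    def _ab(self):
        return (self.low - self.mean) / self.sd, (self.high - self.mean) / self.sd

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        a, b = self._ab()
        return stats.truncnorm.rvs(
            a, b, loc=self.mean, scale=self.sd, size=n, random_state=rng
        )

    def ppf(self, q: np.ndarray) -> np.ndarray:
        a, b = self._ab()
        return stats.truncnorm.ppf(q, a, b, loc=self.mean, scale=self.sd)


@dataclass(frozen=True)
class RMRModelSpec:
    """Per-gender power law RMR/kg = c * k^b over class codes k."""

    c: float  # kcal/kg/day at class 1
    b: float  # dimensionless exponent


@dataclass(frozen=True)
class GeneratorConfig:
    n_male: int
    n_female: int
    age: Dict[Gender, TruncNormalSpec]
    weight: Dict[Gender, TruncNormalSpec]
    height: Dict[Gender, TruncNormalSpec]
    rmr_model: Dict[Gender, RMRModelSpec]
    noise_sd_log10: float = 0.04
    weight_height_rho: float = 0.4
    education_base: tuple = (0.20, 0.45, 0.35)  # primary, secondary, tertiary
    tertiary_normal_odds: float = 1.5
    rmr_regressor: str = "class_code"  # or "bmi" (non-canonical mirror mode)
    seed: int = 0

    def __post_init__(self):
        if self.n_male < 0 or self.n_female < 0:
            raise GeneratorConfigError("counts must be >= 0")
        if self.noise_sd_log10 < 0:
            raise GeneratorConfigError("noise sd must be >= 0")
        if not -1 < self.weight_height_rho < 1:
            raise GeneratorConfigError("rho must be in (-1, 1)")
        if self.rmr_regressor not in {"class_code", "bmi"}:
            raise GeneratorConfigError("rmr_regressor must be class_code or bmi")
        if abs(sum(self.education_base) - 1) > 1e-9:
            raise GeneratorConfigError("education probabilities must sum to 1")


def default_config(seed: int = 0) -> GeneratorConfig:
    """Study-population defaults: 105 men / 278 women, the per-gender
    anthropometric moments and ranges above, and the gender power laws
    (men c=25.41, b=-0.2115; women c=21.09, b=-0.1786)."""
    return GeneratorConfig(
        n_male=105,
        n_female=278,
        age={
            Gender.MALE: TruncNormalSpec(37.5, 15.0, 10, 77),
            Gender.FEMALE: TruncNormalSpec(37.5, 14.0, 12, 76),
        },
        weight={
            Gender.MALE: TruncNormalSpec(100.1, 23.1, 59.0, 177.0),
            Gender.FEMALE: TruncNormalSpec(79.7, 20.0, 42.7, 166.0),
        },
        height={
            Gender.MALE: TruncNormalSpec(1.76, 0.08, 1.44, 1.98),
            Gender.FEMALE: TruncNormalSpec(1.63, 0.06, 1.48, 1.86),
        },
        rmr_model={
            Gender.MALE: RMRModelSpec(c=25.41, b=-0.2115),
            Gender.FEMALE: RMRModelSpec(c=21.09, b=-0.1786),
        },
        seed=seed,
    )


def _sample_education(
    rng: np.random.Generator, config: GeneratorConfig, is_normal_weight: np.ndarray
) -> List[Education]:
    p_base = np.array(config.education_base, dtype=float)
    # odds tilt on the tertiary share for normal-weight subjects
    odds = p_base / (1 - p_base)
    odds_tilted = odds.copy()
    odds_tilted[2] *= config.tertiary_normal_odds
    p_tilt = odds_tilted / (1 + odds_tilted)
    p_tilt /= p_tilt.sum()
    levels = [Education.PRIMARY, Education.SECONDARY, Education.TERTIARY]
    out = []
    for normal in is_normal_weight:
        p = p_tilt if normal else p_base
        out.append(levels[rng.choice(3, p=p)])
    return out


def _generate_gender(
    rng: np.random.Generator, config: GeneratorConfig, gender: Gender, n: int, start: int
) -> List[Subject]:
    # Gaussian copula for (weight, height); age independent.
    cov = np.array([[1.0, config.weight_height_rho], [config.weight_height_rho, 1.0]])
    z = rng.multivariate_normal(np.zeros(2), cov, size=n)
    u = stats.norm.cdf(z)
    weight = config.weight[gender].ppf(u[:, 0])
    height = config.height[gender].ppf(u[:, 1])
    age = np.round(config.age[gender].sample(rng, n)).astype(int)
    age = np.clip(age, int(np.ceil(config.age[gender].low)),
                  int(np.floor(config.age[gender].high)))

    model = config.rmr_model[gender]
    eps = rng.normal(0.0, config.noise_sd_log10, size=n)
    codes = np.array(
        [classify_bmi(w, h).code for w, h in zip(weight, height)], dtype=float
    )
    if config.rmr_regressor == "class_code":
        k = np.maximum(codes, 1.0)
    else:
        k = weight / height**2
    rmr_per_kg = model.c * k**model.b * 10.0**eps
    rmr = rmr_per_kg * weight

    is_normal = codes == 1
    education = _sample_education(rng, config, is_normal)

    prefix = "M" if gender is Gender.MALE else "F"
    return [
        Subject(
            id=f"{prefix}{start + i:04d}",
            gender=gender,
            age=int(age[i]),
            weight_kg=float(weight[i]),
            height_m=float(height[i]),
            education=education[i],
            rmr_kcal_day=float(rmr[i]),
        )
        for i in range(n)
    ]


def generate_cohort(
    config: Optional[GeneratorConfig] = None, seed: Optional[int] = None
) -> List[Subject]:
    """Generate a cohort of n_male + n_female subjects.

    ``seed`` overrides ``config.seed``; the same (config, seed) pair is
    bit-reproducible.
    """
    if config is None:
        config = default_config()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    males = _generate_gender(rng, config, Gender.MALE, config.n_male, 1)
    females = _generate_gender(rng, config, Gender.FEMALE, config.n_female, 1)
    return males + females
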