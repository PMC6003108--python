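"""Power-law model of per-kg RMR against BMI class.

Measured RMR per kilogram of body weight declines with BMI class.  The
model fitted here is

    RMR (kcal/kg/day) = c * k^b,     k = BMI class code (1..5)

estimated as ordinary least squares of log10(class mean RMR/kg) on
log10(k) — the regressor is the integer class code, not raw BMI.  The
canonical fit uses the five class means (this is what makes R^2 values
near 99% attainable); per-subject and raw-BMI variants are offered for
sensitivity analysis and are explicitly non-canonical.

With both genders pooled the cohort model here yields c ≈ 21.5 and
b ≈ -0.15; gender-specific fits give a steeper male decline than
female.  Predictions convert back to kcal/day by multiplying by body
weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Gender, Subject, analysis_subjects


class BMIFitError(ValueError):
    pass


@dataclass
class ClassMeans:
    """Per-BMI-class mean RMR/kg with t-based 95% CI and counts."""

    table: pd.DataFrame  # index: class code; columns mean, ci_low, ci_high, n

    @property
    def codes(self) -> np.ndarray:
        return self.table.index.to_numpy()

    @property
    def means(self) -> np.ndarray:
        return self.table["mean"].to_numpy()


@dataclass(frozen=True)
class PowerLawFit:
    """c * k^b in power form; intercept/slope in log10-log10 space."""

    coefficient: float  # c = 10**intercept, kcal/kg/day
    exponent: float  # b, the log-log slope
    intercept: float
    slope: float
    r2: float
    scope: str = "both"
    n_points: int = 0
    regressor: str = "class_code"


def class_means(
    cohort: Sequence[Subject], gender: Optional[Gender] = None, ci_level: float = 0.95
) -> ClassMeans:
    """Mean measured RMR per kg body weight in each BMI class 1-5.

    Underweight subjects and subjects without a measured RMR are
    skipped; empty classes are omitted with a warning.
    """
    subs = [s for s in analysis_subjects(cohort) if s.rmr_kcal_day is not None]
    if gender is not None:
        subs = [s for s in subs if s.gender == gender]
    if not subs:
        raise BMIFitError("no analysable subjects with measured RMR")

    rows = []
    for code in range(1, 6):
        vals = np.array(
            [s.rmr_kcal_day / s.weight_kg for s in subs if s.bmi_class.code == code]
        )
        if vals.size == 0:
            warnings.warn(f"BMI class {code}: no subjects; omitted")
            continue
        mean = float(vals.mean())
        if vals.size >= 2 and vals.std(ddof=1) > 0:
            half = stats.t.ppf(0.5 + ci_level / 2, vals.size - 1) * vals.std(
                ddof=1
            ) / np.sqrt(vals.size)
        else:
            half = 0.0
        rows.append(
            {
                "class_code": code,
                "mean": mean,
                "ci_low": mean - half,
                "ci_high": mean + half,
                "n": int(vals.size),
            }
        )
    table = pd.DataFrame(rows).set_index("class_code")
    return ClassMeans(table=table)


def _loglog_ols(x: np.ndarray, y: np.ndarray, scope: str, regressor: str) -> PowerLawFit:
    if x.size < 3:
        raise BMIFitError(f"need >= 3 points for the log-log fit, got {x.size}")
    if (x <= 0).any() or (y <= 0).any():
        raise BMIFitError("log-log fit requires positive values")
    res = stats.linregress(np.log10(x), np.log10(y))
    return PowerLawFit(
        coefficient=float(10**res.intercept),
        exponent=float(res.slope),
        intercept=float(res.intercept),
        slope=float(res.slope),
        r2=float(res.rvalue**2),
        scope=scope,
        n_points=int(x.size),
        regressor=regressor,
    )


def fit_power_law(
    data, scope: str = "both", regressor: str = "class_code"
) -> PowerLawFit:
    """OLS power-law fit of RMR/kg on BMI class.

    ``data`` is either a :class:`ClassMeans` (canonical: fit on the
    class means with the integer codes 1-5 as regressor) or a cohort of
    subjects.  For a cohort, ``regressor='class_code'`` fits per-subject
    values against the class code (non-canonical sensitivity variant)
    and ``regressor='bmi'`` against raw BMI (also non-canonical).
    """
    if isinstance(data, ClassMeans):
        if regressor != "class_code":
            raise BMIFitError("class-means fit always uses the class code")
        return _loglog_ols(
            data.codes.astype(float), data.means, scope=scope, regressor=regressor
        )
    subs = [s for s in analysis_subjects(data) if s.rmr_kcal_day is not None]
    if regressor == "class_code":
        x = np.array([float(s.bmi_class.code) for s in subs])
    elif regressor == "bmi":
        x = np.array([s.bmi for s in subs])
    else:
        raise BMIFitError(f"unknown regressor {regressor!r}")
    y = np.array([s.rmr_kcal_day / s.weight_kg for s in subs])
    return _loglog_ols(x, y, scope=scope, regressor=regressor + "_individual")


def fit_power_law_by_gender(cohort: Sequence[Subject]):
    """Canonical class-means fits: pooled, male-only, female-only."""
    fits = {"both": fit_power_law(class_means(cohort), scope="both")}
    for g in Gender:
        fits[g.value] = fit_power_law(class_means(cohort, gender=g), scope=g.value)
    return fits


def predict_new_equation(fit: PowerLawFit, bmi_class: int, weight_kg: float) -> float:
    """Predicted RMR in kcal/day: c * k^b (kcal/kg/day) times weight."""
    if bmi_class == 0:
        raise BMIFitError("underweight (class 0) is outside the fitted model")
    if not 1 <= bmi_class <= 5:
        raise BMIFitError(f"BMI class {bmi_class} outside 1-5")
    if weight_kg <= 0:
        raise BMIFitError("weight must be positive")
    return fit.coefficient * bmi_class**fit.exponent * weight_kg


def fit_report(fits) -> pd.DataFrame:
    """Coefficient/exponent/R^2 frame for a dict of fits keyed by scope."""
    rows = [
        {
            "scope": k,
            "coefficient": f.coefficient,
            "exponent": f.exponent,
            "intercept_log10": f.intercept,
            "r2_pct": 100 * f.r2,
            "n_points": f.n_points,
        }
        for k, f in fits.items()
    ]
    return pd.DataFrame(rows).set_index("scope")


def plot_power_law(cohort: Sequence[Subject], fits, path) -> None:
    """Two-panel log-log figure: pooled fit, and per-gender fits."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))

    def panel(ax, cm: ClassMeans, fit: PowerLawFit, label: str, color=None):
        ax.plot(np.log10(cm.codes), np.log10(cm.means), "o", label=f"{label} means",
                color=color)
        xs = np.linspace(np.log10(1), np.log10(5), 50)
        ax.plot(xs, fit.intercept + fit.slope * xs, "-", color=color,
                label=f"{label}: c={fit.coefficient:.2f}, b={fit.exponent:.3f}")

    panel(axes[0], class_means(cohort), fits["both"], "both")
    for g, color in zip(Gender, ("C0", "C1")):
        panel(axes[1], class_means(cohort, gender=g), fits[g.value], g.value, color)
    for ax in axes:
        ax.set_xlabel("log10(BMI class code)")
        ax.set_ylabel("log10(RMR kcal/kg/day)")
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
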