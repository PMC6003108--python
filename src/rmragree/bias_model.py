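"""Factor regression of per-subject absolute bias.

The absolute bias |estimated - measured| of an equation is right-skewed,
so it is first normalised with a Box-Cox power transformation whose
exponent λ is chosen by profile maximum likelihood on a fixed grid
(default [-1, 1.5] in steps of 0.01 — λ near 0.34-0.41, between log x
and √x, is typical for these biases).  The transformed bias is then
regressed on three categorical predictors — gender, BMI class and age
group — with whole-factor F tests (type-II ANOVA) and backward
elimination: the least significant factor is dropped one at a time until
every retained factor is significant at ``alpha``.

Reference levels are the first level of each factor (female, normal
weight, ages 10-18); this affects coefficients only, not the F tests or
the per-level effect profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

FACTOR_ORDER = ("gender", "bmi_class", "age_group")


class BiasModelError(ValueError):
    pass


def boxcox_lambda(
    values: Sequence[float],
    grid: Tuple[float, float, float] = (-1.0, 1.5, 0.01),
) -> Tuple[float, np.ndarray]:
    """Box-Cox λ by profile log-likelihood over a grid.

    Returns ``(lambda, transformed_values)``.  Values must be strictly
    positive (offsetting is the caller's responsibility) and
    non-degenerate, with at least 10 observations.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 10:
        raise BiasModelError(f"need a 1-d sample of >= 10 values, got {x.shape}")
    if not np.isfinite(x).all() or (x <= 0).any():
        raise BiasModelError("Box-Cox requires finite, strictly positive values")
    if np.ptp(x) == 0:
        raise BiasModelError("degenerate (constant) sample")
    lo, hi, step = grid
    lams = np.arange(lo, hi + step / 2, step)
    # Profile log-likelihood, vectorised over the grid:
    #   llf(l) = (l - 1) sum(log x) - n/2 log(var(x^(l)))
    n = x.size
    logx = np.log(x)
    with np.errstate(over="ignore"):
        y = np.where(
            np.abs(lams[:, None]) < 1e-12,
            logx[None, :],
            (np.exp(lams[:, None] * logx[None, :]) - 1) / np.where(
                np.abs(lams[:, None]) < 1e-12, 1.0, lams[:, None]
            ),
        )
    llf = (lams - 1) * logx.sum() - n / 2.0 * np.log(y.var(axis=1))
    lam = float(lams[int(np.argmax(llf))])
    transformed = stats.boxcox(x, lmbda=lam)
    return lam, transformed


@dataclass
class BiasModelResult:
    """Fitted bias-factor model for one equation."""

    equation: str
    lam: float
    retained: Tuple[str, ...]
    p_values: Dict[str, float]  # final-model p per retained factor
    elimination_path: Dict[str, float] = field(default_factory=dict)  # p at removal
    effect_table: Dict[str, pd.Series] = field(default_factory=dict)
    model: Optional[object] = None  # final statsmodels results (None if empty)


def _collapse_sparse_levels(col: pd.Series, name: str, min_n: int = 2) -> pd.Series:
    """Merge levels with < min_n observations into the nearest level."""
    col = col.copy()
    counts = col.value_counts()
    sparse = counts[counts < min_n].index
    if len(sparse) == 0:
        return col
    levels = sorted(counts.index)
    for lev in sparse:
        others = [l for l in levels if l != lev and counts.get(l, 0) >= min_n]
        if not others:
            continue
        target = min(others, key=lambda l: (abs(_rank(levels, l) - _rank(levels, lev))))
        warnings.warn(
            f"factor {name}: level {lev!r} has < {min_n} observations; "
            f"collapsed into {target!r}"
        )
        col = col.replace({lev: target})
    return col


def _rank(levels, value) -> int:
    return levels.index(value)


def _factor_pvalues(fit, factors) -> Dict[str, float]:
    table = anova_lm(fit, typ=2)
    out = {}
    for f in factors:
        out[f] = float(table.loc[f"C({f})", "PR(>F)"])
    return out


def fit_bias_model(
    abs_bias: Sequence[float],
    factors: pd.DataFrame,
    alpha: float = 0.05,
    equation: str = "",
) -> BiasModelResult:
    """Box-Cox transform then backward-eliminate categorical predictors.

    ``factors`` must have columns gender, bmi_class, age_group aligned
    with ``abs_bias`` (underweight subjects already excluded).  Factors
    whose whole-model F test exceeds ``alpha`` are removed one per step,
    largest p first (ties broken in the order gender, bmi_class,
    age_group); a factor left with a single level after sparse-level
    collapsing is dropped up front.
    """
    y = np.asarray(abs_bias, dtype=float)
    if len(factors) != y.size:
        raise BiasModelError("abs_bias and factors are not aligned")
    missing = [c for c in FACTOR_ORDER if c not in factors.columns]
    if missing:
        raise BiasModelError(f"missing factor column(s): {missing}")

    lam, z = boxcox_lambda(y)
    df = factors.loc[:, list(FACTOR_ORDER)].copy()
    df["z"] = z

    candidates = []
    for f in FACTOR_ORDER:
        df[f] = _collapse_sparse_levels(df[f].astype(str), f)
        if df[f].nunique() >= 2:
            candidates.append(f)
        else:
            warnings.warn(f"factor {f}: single level after collapsing; dropped")

    elimination_path: Dict[str, float] = {}
    current = list(candidates)
    fit = None
    while current:
        formula = "z ~ " + " + ".join(f"C({f})" for f in current)
        fit = ols(formula, data=df).fit()
        pvals = _factor_pvalues(fit, current)
        worst = max(
            current, key=lambda f: (pvals[f], -FACTOR_ORDER.index(f))
        )
        if pvals[worst] <= alpha:
            break
        elimination_path[worst] = pvals[worst]
        current.remove(worst)
        fit = None

    if current and fit is not None:
        p_values = _factor_pvalues(fit, current)
    else:
        p_values = {}
        fit = None

    effect_table = {
        f: df.groupby(f, observed=True)["z"].mean().sort_index() for f in current
    }
    return BiasModelResult(
        equation=equation,
        lam=lam,
        retained=tuple(f for f in FACTOR_ORDER if f in current),
        p_values=p_values,
        elimination_path=elimination_path,
        effect_table=effect_table,
        model=fit,
    )


def effects_profile(
    result: BiasModelResult, factors: Optional[pd.DataFrame] = None,
    abs_bias: Optional[Sequence[float]] = None,
) -> Dict[str, pd.Series]:
    """Per-level means of the transformed bias for each retained factor.

    With no extra arguments this returns the profiles stored on the
    fitted result (the input to a main-effects plot).  Passing the
    original ``factors``/``abs_bias`` recomputes profiles for *all*
    factors, retained or not.
    """
    if factors is None or abs_bias is None:
        return dict(result.effect_table)
    _, z = boxcox_lambda(np.asarray(abs_bias, dtype=float))
    df = factors.copy()
    df["z"] = z
    return {
        f: df.groupby(f, observed=True)["z"].mean().sort_index()
        for f in FACTOR_ORDER
        if f in df.columns
    }


def bias_model_table(results: Sequence[BiasModelResult]) -> pd.DataFrame:
    """Summary frame: one row per equation, λ and p per factor."""
    rows = []
    for r in results:
        row = {"equation": r.equation, "lambda": r.lam}
        for f in FACTOR_ORDER:
            row[f"p_{f}"] = r.p_values.get(f, np.nan)
        rows.append(row)
    return pd.DataFrame(rows).set_index("equation")
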