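"""Method-comparison statistics between measured and estimated RMR.

For each prediction equation the summary reports the descriptive
statistics of its estimates, the mean bias (mean over subjects of
estimated minus measured, positive = overestimation) with a two-sided
95% t confidence interval, the absolute bias |mean(measured) -
mean(estimated)|, and the percentage accuracy in both directions:

    accuracy_vs_m = absolute bias * 100 / mean(measured)
    accuracy_vs_e = absolute bias * 100 / mean(estimated)

Deviations below 10% are conventionally deemed adequate.  ``n_within_10``
counts subjects whose individual deviation |RMRe - RMRm| * 100 / RMRm is
at most 10%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .equations import PredictionMatrix


class AgreementError(ValueError):
    pass


@dataclass(frozen=True)
class AgreementSummary:
    equation: str
    n: int
    min: float
    max: float
    mean: float
    sd: float
    mean_bias: float
    bias_ci: Tuple[float, float]
    abs_bias: float
    accuracy_vs_m: float
    accuracy_vs_e: float
    n_within_10: int


def summarize_agreement(
    rmr_measured: Sequence[float],
    rmr_estimated: Sequence[float],
    equation: str = "",
    ci_level: float = 0.95,
) -> AgreementSummary:
    """Paired agreement summary for one equation.

    Inputs must be equal-length, finite and positive, with excluded
    subjects already removed.  The bias CI is the t interval on the mean
    of the individual biases.
    """
    m = np.asarray(rmr_measured, dtype=float)
    e = np.asarray(rmr_estimated, dtype=float)
    if m.shape != e.shape or m.ndim != 1:
        raise AgreementError("measured and estimated series must be paired 1-d")
    if m.size < 3:
        raise AgreementError(f"need at least 3 pairs, got {m.size}")
    if not (np.isfinite(m).all() and np.isfinite(e).all()):
        raise AgreementError("non-finite RMR value")
    if (m <= 0).any() or (e <= 0).any():
        raise AgreementError("non-positive RMR value")

    bias = e - m
    n = int(m.size)
    mean_bias = float(bias.mean())
    sd_bias = float(bias.std(ddof=1))
    tcrit = stats.t.ppf(0.5 + ci_level / 2.0, df=n - 1)
    half = tcrit * sd_bias / np.sqrt(n)
    abs_bias = abs(float(m.mean()) - float(e.mean()))
    pct_dev = np.abs(bias) * 100.0 / m
    return AgreementSummary(
        equation=equation,
        n=n,
        min=float(e.min()),
        max=float(e.max()),
        mean=float(e.mean()),
        sd=float(e.std(ddof=1)),
        mean_bias=mean_bias,
        bias_ci=(mean_bias - half, mean_bias + half),
        abs_bias=abs_bias,
        accuracy_vs_m=abs_bias * 100.0 / float(m.mean()),
        accuracy_vs_e=abs_bias * 100.0 / float(e.mean()),
        n_within_10=int((pct_dev <= 10.0).sum()),
    )


def adequacy_flag(summary: AgreementSummary, threshold: float = 10.0) -> bool:
    """True iff both accuracy percentages are strictly below the threshold."""
    return summary.accuracy_vs_m < threshold and summary.accuracy_vs_e < threshold


def agreement_table(matrix: PredictionMatrix, specs=None) -> pd.DataFrame:
    """Per-equation agreement summary over the analysis subjects.

    Underweight subjects and subjects without a measured RMR are
    dropped.  Returns one leading row of measured-RMR descriptives
    followed by one row per equation, ordered by covariate category then
    config order when ``specs`` is given.
    """
    keep = (~matrix.excluded) & matrix.measured.notna()
    measured = matrix.measured[keep]
    est = matrix.estimates.loc[keep]
    if measured.size < 3:
        raise AgreementError("fewer than 3 analysable subjects")

    order = list(est.columns)
    if specs is not None:
        cat = {s.name: s.category for s in specs}
        pos = {s.name: i for i, s in enumerate(specs)}
        order.sort(key=lambda n: (cat.get(n, 99), pos.get(n, 99)))

    rows = [
        {
            "equation": "RMRm",
            "n": int(measured.size),
            "min": float(measured.min()),
            "max": float(measured.max()),
            "mean": float(measured.mean()),
            "sd": float(measured.std(ddof=1)),
        }
    ]
    for name in order:
        s = summarize_agreement(measured.values, est[name].values, equation=name)
        rows.append(
            {
                "equation": s.equation,
                "n": s.n,
                "min": s.min,
                "max": s.max,
                "mean": s.mean,
                "sd": s.sd,
                "mean_bias": s.mean_bias,
                "bias_ci_low": s.bias_ci[0],
                "bias_ci_high": s.bias_ci[1],
                "abs_bias": s.abs_bias,
                "accuracy_vs_m_pct": s.accuracy_vs_m,
                "accuracy_vs_e_pct": s.accuracy_vs_e,
                "n_within_10": s.n_within_10,
                "adequate": adequacy_flag(s),
            }
        )
    return pd.DataFrame(rows).set_index("equation")


def format_agreement_table(table: pd.DataFrame) -> str:
    """Display formatting: kcal columns to integers, percentages to 0.1."""
    disp = table.copy()
    for col in ("min", "max", "mean", "sd", "mean_bias", "bias_ci_low",
                "bias_ci_high", "abs_bias"):
        if col in disp:
            disp[col] = disp[col].round(0).astype("Int64")
    for col in ("accuracy_vs_m_pct", "accuracy_vs_e_pct"):
        if col in disp:
            disp[col] = disp[col].round(1)
    return disp.to_string()
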