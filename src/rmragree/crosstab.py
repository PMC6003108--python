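"""Chi-square independence tests between BMI classes and cohort factors.

Pearson's chi-square test of independence on the contingency table of a
categorical factor (gender, age group or education) against BMI classes
1-5, with per-cell standardized residuals (O - E)/sqrt(E).  Cells with
|residual| > 2 are flagged as over- or under-represented.  Adjusted
residuals (O - E)/sqrt(E (1 - p_row)(1 - p_col)) are available as an
option.  Underweight subjects are excluded throughout, as are
unknown-education subjects when education is the factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Education, Subject, analysis_subjects

RESIDUAL_FLAG_THRESHOLD = 2.0


class CrosstabError(ValueError):
    pass


@dataclass
class CrosstabResult:
    factor: str
    table: pd.DataFrame  # observed counts, rows = factor levels
    expected: pd.DataFrame
    chi2: float
    df: int
    p: float
    std_residuals: pd.DataFrame
    flags: pd.DataFrame  # long format: level, bmi_class, residual, direction
    warnings: List[str] = field(default_factory=list)


def crosstab_from_table(
    observed: pd.DataFrame, factor: str = "", adjusted: bool = False
) -> CrosstabResult:
    """Chi-square test on an observed contingency table.

    Rows are factor levels, columns BMI classes (or any second factor).
    No continuity correction is applied.
    """
    obs = observed.astype(float)
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise CrosstabError(f"need at least a 2x2 table, got {obs.shape}")
    if (obs.values < 0).any():
        raise CrosstabError("negative counts")
    chi2, p, dof, expected = stats.chi2_contingency(obs.values, correction=False)
    exp = pd.DataFrame(expected, index=obs.index, columns=obs.columns)

    resid = (obs - exp) / np.sqrt(exp)
    if adjusted:
        n = obs.values.sum()
        row_p = obs.sum(axis=1) / n
        col_p = obs.sum(axis=0) / n
        adj = np.sqrt(np.outer(1 - row_p, 1 - col_p))
        resid = resid / pd.DataFrame(adj, index=obs.index, columns=obs.columns)

    warns = []
    if (expected < 1).any():
        warns.append("some expected cell counts are below 1; chi-square may be invalid")
    elif (expected < 5).any():
        warns.append("some expected cell counts are below 5")

    flagged = []
    for lev in resid.index:
        for col in resid.columns:
            r = resid.loc[lev, col]
            if abs(r) > RESIDUAL_FLAG_THRESHOLD:
                flagged.append(
                    {
                        "level": lev,
                        "column": col,
                        "residual": float(r),
                        "direction": "over" if r > 0 else "under",
                    }
                )
    flags = pd.DataFrame(flagged, columns=["level", "column", "residual", "direction"])
    for w in warns:
        warnings.warn(w)
    return CrosstabResult(
        factor=factor,
        table=obs,
        expected=exp,
        chi2=float(chi2),
        df=int(dof),
        p=float(p),
        std_residuals=resid,
        flags=flags,
        warnings=warns,
    )


def crosstab_test(
    cohort: Sequence[Subject], factor: str, adjusted: bool = False
) -> CrosstabResult:
    """Test independence of a cohort factor and BMI class (codes 1-5)."""
    if factor not in {"gender", "age_group", "education"}:
        raise CrosstabError(f"unsupported factor {factor!r}")
    subs = analysis_subjects(cohort)
    if factor == "education":
        subs = [s for s in subs if s.education != Education.UNKNOWN]

    def level(s: Subject):
        if factor == "gender":
            return s.gender.value
        if factor == "age_group":
            return s.age_group.label
        return s.education.value

    df = pd.DataFrame(
        {"level": [level(s) for s in subs], "bmi": [s.bmi_class.code for s in subs]}
    )
    observed = pd.crosstab(df["level"], df["bmi"])
    observed = observed.loc[:, [c for c in sorted(observed.columns)]]
    if observed.shape[0] < 2:
        raise CrosstabError(f"factor {factor}: fewer than 2 non-empty levels")
    return crosstab_from_table(observed, factor=factor, adjusted=adjusted)
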