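"""Library of RMR prediction equations with gender / age-bracket dispatch.

The equations compared here are linear in a subject's covariates
(weight, height, age, BMI) with coefficients that depend on gender and,
for the Schofield and FAO/WHO/UNU families, on an age bracket.  All
output kcal/day.  Coefficients live in an editable YAML config rather
than code; :func:`default_equations` loads the bundled tables
(Harris-Benedict original / revised / abbreviated, Mifflin-St Jeor,
Owen, Schofield, FAO/WHO/UNU weight+height and weight-only, plus a
placeholder slot for a BMI-based equation).

Equation categories (by covariates used):

1. weight, height, age, gender
2. weight, height, age group, gender
3. weight, age group, gender
4. weight, gender
5. BMI, age, gender
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml

from .cohort import Gender, Subject

logger = logging.getLogger(__name__)

VALID_COVARIATES = {"weight", "height", "age", "age_group", "gender", "bmi"}


class EquationConfigError(ValueError):
    """Malformed equation configuration."""


class DispatchError(LookupError):
    """No coefficient row matches a subject's gender/age cell."""


@dataclass(frozen=True)
class CoefficientRow:
    """Linear coefficients for one (gender, age-bracket) cell."""

    gender: Gender
    age_min: int
    age_max: int
    intercept: float
    weight: float = 0.0
    height: float = 0.0
    age: float = 0.0
    bmi: float = 0.0


@dataclass(frozen=True)
class EquationSpec:
    """A named prediction equation: covariates plus per-cell coefficients.

    ``height_unit`` says which unit the height coefficient multiplies
    ('cm' or 'm'); subjects store metres and are converted on the fly.
    Placeholder specs (no coefficient rows) are valid config entries but
    cannot predict.
    """

    name: str
    category: int
    covariates: frozenset
    rows: tuple = ()
    height_unit: str = "m"
    placeholder: bool = False

    def rows_for(self, gender: Gender) -> list:
        return [r for r in self.rows if r.gender == gender]

    def dispatch(self, gender: Gender, age: int) -> CoefficientRow:
        """Coefficient row for the cell; lower bracket wins a shared bound."""
        for row in self.rows_for(gender):
            if row.age_min <= age <= row.age_max:
                return row
        raise DispatchError(
            f"{self.name}: no coefficient row for gender={gender.value}, age={age}"
        )


def _validate_brackets(spec: EquationSpec) -> None:
    for gender in Gender:
        rows = sorted(spec.rows_for(gender), key=lambda r: r.age_min)
        if not rows:
            raise EquationConfigError(
                f"{spec.name}: no coefficient row for gender {gender.value}"
            )
        if rows[0].age_min > 10 or rows[-1].age_max < 120:
            raise EquationConfigError(
                f"{spec.name}/{gender.value}: brackets do not cover ages 10-120"
            )
        for prev, nxt in zip(rows, rows[1:]):
            if nxt.age_min < prev.age_max:
                raise EquationConfigError(
                    f"{spec.name}/{gender.value}: overlapping age brackets "
                    f"{prev.age_min}-{prev.age_max} and {nxt.age_min}-{nxt.age_max}"
                )
            if nxt.age_min > prev.age_max + 1:
                raise EquationConfigError(
                    f"{spec.name}/{gender.value}: gap between age brackets "
                    f"{prev.age_min}-{prev.age_max} and {nxt.age_min}-{nxt.age_max}"
                )


def _spec_from_dict(block: dict) -> EquationSpec:
    covs = set(block.get("covariates", []))
    unknown = covs - VALID_COVARIATES
    if unknown:
        raise EquationConfigError(
            f"{block.get('name', '?')}: unknown covariate(s) {sorted(unknown)}"
        )
    rows = tuple(
        CoefficientRow(
            gender=Gender.parse(r["gender"]),
            age_min=int(r["age_min"]),
            age_max=int(r["age_max"]),
            intercept=float(r["intercept"]),
            weight=float(r.get("weight", 0.0)),
            height=float(r.get("height", 0.0)),
            age=float(r.get("age", 0.0)),
            bmi=float(r.get("bmi", 0.0)),
        )
        for r in block.get("rows", [])
    )
    spec = EquationSpec(
        name=str(block["name"]),
        category=int(block["category"]),
        covariates=frozenset(covs),
        rows=rows,
        height_unit=str(block.get("height_unit", "m")),
        placeholder=bool(block.get("placeholder", False)),
    )
    if spec.height_unit not in {"m", "cm"}:
        raise EquationConfigError(f"{spec.name}: height_unit must be 'm' or 'cm'")
    if not spec.placeholder:
        _validate_brackets(spec)
    elif spec.rows:
        raise EquationConfigError(f"{spec.name}: placeholder spec must have no rows")
    return spec


def load_equation_config(path) -> list:
    """Load and validate equation specs from a YAML file."""
    with Path(path).open() as fh:
        blocks = yaml.safe_load(fh)
    if not isinstance(blocks, list):
        raise EquationConfigError(f"{path}: expected a list of equation blocks")
    specs = [_spec_from_dict(b) for b in blocks]
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise EquationConfigError("duplicate equation names in config")
    return specs


def default_equations() -> list:
    """The bundled nine-equation default configuration."""
    ref = resources.files("rmragree").joinpath("data/equations.yaml")
    with resources.as_file(ref) as path:
        return load_equation_config(path)


def predict(subject: Subject, spec: EquationSpec) -> float:
    """Estimated RMR (kcal/day) for one subject under one equation."""
    if spec.placeholder:
        raise EquationConfigError(
            f"{spec.name}: placeholder equation has no coefficients configured"
        )
    row = spec.dispatch(subject.gender, subject.age)
    height = subject.height_m * (100.0 if spec.height_unit == "cm" else 1.0)
    value = (
        row.intercept
        + row.weight * subject.weight_kg
        + row.height * height
        + row.age * subject.age
        + row.bmi * subject.bmi
    )
    if not (value > 0):
        raise ValueError(
            f"{spec.name}: non-positive prediction {value!r} for subject {subject.id}"
        )
    return value


@dataclass
class PredictionMatrix:
    """Per-subject, per-equation estimated RMR (kcal/day).

    ``excluded`` marks underweight subjects: they are predicted like any
    other (exclusion applies only to the statistics stages).
    """

    estimates: pd.DataFrame  # index: subject id, columns: equation name
    excluded: pd.Series  # bool per subject id
    measured: pd.Series  # measured RMR per subject id (NaN if absent)


def predict_all(
    cohort: Sequence[Subject], specs: Iterable[EquationSpec]
) -> PredictionMatrix:
    """Predict every equation for every subject.

    Placeholder specs are skipped with a warning; per-subject dispatch
    failures propagate annotated with the subject id.
    """
    specs = list(specs)
    if not cohort:
        raise ValueError("empty cohort")
    active = [s for s in specs if not s.placeholder]
    for s in specs:
        if s.placeholder:
            warnings.warn(
                f"equation {s.name} is a placeholder (no coefficients); skipped"
            )
    if not active:
        warnings.warn("no active equation specs; prediction matrix is empty")

    ids = [s.id for s in cohort]
    data = {}
    for spec in active:
        col = []
        for subj in cohort:
            try:
                col.append(predict(subj, spec))
            except DispatchError as exc:
                raise DispatchError(f"subject {subj.id}: {exc}") from exc
        data[spec.name] = col
    estimates = pd.DataFrame(data, index=pd.Index(ids, name="id"), dtype=float)
    excluded = pd.Series([s.excluded for s in cohort], index=estimates.index)
    measured = pd.Series(
        [float("nan") if s.rmr_kcal_day is None else s.rmr_kcal_day for s in cohort],
        index=estimates.index,
        dtype=float,
    )
    return PredictionMatrix(estimates=estimates, excluded=excluded, measured=measured)
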