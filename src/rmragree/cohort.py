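"""Domain types and classification rules for an RMR study cohort.

A cohort is a collection of :class:`Subject` records: anthropometrics
(weight in kg, height in m), demographics (gender, integer age in years,
optional education level) and, where available, a resting metabolic rate
measured by indirect calorimetry (kcal/day).

Two classifications drive every downstream analysis stage:

* WHO BMI classes, coded 0-5.  Code 0 (underweight, BMI < 18.5) is
  retained in the data model but flagged as excluded from statistics,
  mirroring the common practice of dropping a handful of underweight
  subjects from adult-cohort analyses.  Codes 1-5 (normal weight through
  obesity class III) are the regressor values of the BMI-class power-law
  model in :mod:`rmragree.bmi_fit`.
* Age groups 10-18, 19-30, 31-45, 46-60 and 61+ (codes 1-5), a gap-free
  partition of the supported ages.

Heights are stored in metres everywhere; prediction equations that want
centimetres convert internally.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union


class CohortError(ValueError):
    """Invalid subject data or classification input."""


class Gender(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"

    @classmethod
    def parse(cls, token: str) -> "Gender":
        t = str(token).strip().lower()
        if t in {"m", "male"}:
            return cls.MALE
        if t in {"f", "female"}:
            return cls.FEMALE
        raise CohortError(f"unrecognised gender token: {token!r}")


class Education(str, enum.Enum):
    PRIMARY = "primary"
    SECONDARY = "secondary"
    TERTIARY = "tertiary"
    UNKNOWN = "unknown"

    @classmethod
    def parse(cls, token) -> "Education":
        t = str(token).strip().lower()
        if t in {"", "na", "nan", "none", "unknown"}:
            return cls.UNKNOWN
        try:
            return cls(t)
        except ValueError:
            raise CohortError(f"unrecognised education token: {token!r}") from None


BMI_CLASS_LABELS = {
    0: "underweight",
    1: "normal",
    2: "overweight",
    3: "obese_I",
    4: "obese_II",
    5: "obese_III",
}

# WHO cutoffs, lower-inclusive: [18.5, 25) is normal weight, etc.
_BMI_CUTOFFS = (18.5, 25.0, 30.0, 35.0, 40.0)

AGE_GROUP_LABELS = {1: "10-18", 2: "19-30", 3: "31-45", 4: "46-60", 5: ">60"}
_AGE_UPPER = (18, 30, 45, 60)  # inclusive upper bounds of groups 1-4


@dataclass(frozen=True)
class BMIClass:
    """WHO BMI class with the integer code used as regressor downstream."""

    code: int
    label: str = field(compare=False)

    @property
    def excluded(self) -> bool:
        """Underweight subjects are excluded from all statistics."""
        return self.code == 0


@dataclass(frozen=True)
class AgeGroup:
    code: int
    label: str = field(compare=False)


def compute_bmi(weight_kg: float, height_m: float) -> float:
    """BMI in kg/m^2; weight and height must be strictly positive."""
    if not (weight_kg > 0 and height_m > 0):
        raise CohortError(
            f"weight and height must be positive, got {weight_kg}, {height_m}"
        )
    return weight_kg / height_m**2


def classify_bmi(weight_kg: float, height_m: float) -> BMIClass:
    """WHO BMI class for the given anthropometrics.

    Cutoffs are lower-inclusive: <18.5 underweight (code 0, flagged
    excluded), [18.5, 25) normal, [25, 30) overweight, [30, 35) obese I,
    [35, 40) obese II, >=40 obese III.
    """
    bmi = compute_bmi(weight_kg, height_m)
    code = sum(bmi >= c for c in _BMI_CUTOFFS)
    return BMIClass(code=code, label=BMI_CLASS_LABELS[code])


def classify_age(age_years: Union[int, float]) -> AgeGroup:
    """Age group for an integer age in years; supported range starts at 10."""
    if age_years < 10:
        raise CohortError(f"age {age_years} below supported range (>= 10 years)")
    code = 1 + sum(age_years > u for u in _AGE_UPPER)
    return AgeGroup(code=code, label=AGE_GROUP_LABELS[code])


@dataclass(frozen=True)
class Subject:
    """One study participant.

    ``rmr_kcal_day`` is the calorimetry-measured resting metabolic rate
    and may be absent (prediction-only use).
    """

    id: str
    gender: Gender
    age: int
    weight_kg: float
    height_m: float
    education: Education = Education.UNKNOWN
    rmr_kcal_day: Optional[float] = None

    def __post_init__(self):
        if self.weight_kg <= 0:
            raise CohortError(f"subject {self.id}: non-positive weight")
        if self.height_m <= 0:
            raise CohortError(f"subject {self.id}: non-positive height")
        if self.age < 0:
            raise CohortError(f"subject {self.id}: negative age")
        if self.rmr_kcal_day is not None and self.rmr_kcal_day <= 0:
            raise CohortError(f"subject {self.id}: non-positive measured RMR")

    @property
    def bmi(self) -> float:
        return compute_bmi(self.weight_kg, self.height_m)

    @property
    def bmi_class(self) -> BMIClass:
        return classify_bmi(self.weight_kg, self.height_m)

    @property
    def age_group(self) -> AgeGroup:
        return classify_age(self.age)

    @property
    def excluded(self) -> bool:
        """True for underweight subjects, which all statistics skip."""
        return self.bmi_class.excluded


COLUMNS = ("id", "gender", "age", "weight_kg", "height_m", "education", "rmr_kcal_day")
_MANDATORY = ("id", "gender", "age", "weight_kg", "height_m")


@dataclass
class CohortReadResult:
    """Validated subjects plus per-row rejection reports."""

    subjects: list
    rejected: list  # (1-based data row number, reason)

    @property
    def n_accepted(self) -> int:
        return len(self.subjects)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def _parse_row(row: dict, rownum: int) -> Subject:
    try:
        rmr_raw = row.get("rmr_kcal_day", "")
        rmr = None
        if rmr_raw not in (None, "", "na", "NA", "nan"):
            rmr = float(rmr_raw)
        return Subject(
            id=str(row["id"]),
            gender=Gender.parse(row["gender"]),
            age=int(float(row["age"])),
            weight_kg=float(row["weight_kg"]),
            height_m=float(row["height_m"]),
            education=Education.parse(row.get("education", "")),
            rmr_kcal_day=rmr,
        )
    except CohortError:
        raise
    except (KeyError, TypeError, ValueError) as exc:
        raise CohortError(f"unparseable field: {exc}") from exc


def read_cohort(path, delimiter: Optional[str] = None) -> CohortReadResult:
    """Read a subject table from delimited text.

    The file must have a header row; lines starting with ``#`` are
    treated as comments.  Rows violating subject invariants are rejected
    individually and reported with their data row number and reason; a
    missing mandatory column aborts with a schema error.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    if not lines:
        raise CohortError(f"{path}: empty file")
    if delimiter is None:
        delimiter = "\t" if "\t" in lines[0] else ","
    reader = csv.DictReader(lines, delimiter=delimiter)
    header = [h.strip() for h in (reader.fieldnames or [])]
    missing = [c for c in _MANDATORY if c not in header]
    if missing:
        raise CohortError(f"{path}: missing mandatory column(s) {missing}")

    subjects, rejected = [], []
    for i, row in enumerate(reader, start=1):
        try:
            subjects.append(_parse_row(row, i))
        except CohortError as exc:
            rejected.append((i, str(exc)))
    return CohortReadResult(subjects=subjects, rejected=rejected)


def write_cohort(subjects: Iterable[Subject], path, header_comment: str = "") -> None:
    """Write subjects as CSV readable by :func:`read_cohort`."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        writer = csv.writer(fh)
        writer.writerow(COLUMNS)
        for s in subjects:
            writer.writerow(
                [
                    s.id,
                    s.gender.value,
                    s.age,
                    f"{s.weight_kg:.6g}",
                    f"{s.height_m:.6g}",
                    s.education.value,
                    "" if s.rmr_kcal_day is None else f"{s.rmr_kcal_day:.6g}",
                ]
            )


def analysis_subjects(subjects: Sequence[Subject]) -> list:
    """Subjects entering the statistics: underweight excluded."""
    return [s for s in subjects if not s.excluded]
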