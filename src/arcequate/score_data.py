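"""Subject-level paired-score data model, CSV I/O, stratification and splitting.

A :class:`Cohort` is an ordered collection of :class:`SubjectRecord`, each
carrying one patient's demographics plus paired MMSE and MoCA totals on the
0-30 scale.  Cohorts are read from and written to a simple CSV schema
(``subject_id,age,sex,education_years,mmse,moca[,group]``), can be
partitioned into education strata, and can be split reproducibly into a
conversion group A and a validation group B.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CohortValidationError, SchemaError

SCORE_MIN = 0
SCORE_MAX = 30

REQUIRED_COLUMNS = ("subject_id", "age", "sex", "education_years", "mmse", "moca")
OPTIONAL_COLUMNS = ("group",)

_SEX_ALIASES = {
    "m": "male", "male": "male", "1": "male",
    "f": "female", "female": "female", "0": "female",
}


def normalize_sex(value) -> str:
    """Map tolerant file encodings {M,F,male,female,0,1} to {male, female}."""
    key = str(value).strip().lower()
    if key not in _SEX_ALIASES:
        raise CohortValidationError(f"unrecognized sex value {value!r}")
    return _SEX_ALIASES[key]


@dataclass(frozen=True)
class SubjectRecord:
    """One patient: demographics plus paired integer MMSE/MoCA totals."""

    subject_id: str
    age: float
    sex: str  # "male" | "female"
    education_years: int
    mmse: int
    moca: int
    group: str | None = None  # "A" | "B" | None

    def __post_init__(self) -> None:
        if not SCORE_MIN <= self.mmse <= SCORE_MAX:
            raise CohortValidationError(
                f"subject {self.subject_id}: mmse={self.mmse} outside [0, 30]")
        if not SCORE_MIN <= self.moca <= SCORE_MAX:
            raise CohortValidationError(
                f"subject {self.subject_id}: moca={self.moca} outside [0, 30]")
        if self.education_years < 0:
            raise CohortValidationError(
                f"subject {self.subject_id}: negative education_years")
        if self.age < 0:
            raise CohortValidationError(f"subject {self.subject_id}: negative age")
        if self.sex not in ("male", "female"):
            raise CohortValidationError(
                f"subject {self.subject_id}: sex must be 'male' or 'female'")
        if self.group is not None and self.group not in ("A", "B"):
            raise CohortValidationError(
                f"subject {self.subject_id}: group must be 'A', 'B' or absent")


@dataclass
class Cohort:
    """Ordered collection of subject records with unique ids."""

    records: list[SubjectRecord] = field(default_factory=list)
    label: str = ""
    metadata: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate subject ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SubjectRecord]:
        return iter(self.records)

    @property
    def mmse(self) -> np.ndarray:
        return np.array([r.mmse for r in self.records], dtype=int)

    @property
    def moca(self) -> np.ndarray:
        return np.array([r.moca for r in self.records], dtype=int)

    def pairs(self) -> list[tuple[int, int]]:
        """Paired (mmse, moca) scores in record order."""
        return [(r.mmse, r.moca) for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        cols = {c: [getattr(r, c) for r in self.records] for c in REQUIRED_COLUMNS}
        frame = pd.DataFrame(cols)
        groups = [r.group for r in self.records]
        if any(g is not None for g in groups):
            frame["group"] = groups
        return frame

    def relabel(self, label: str) -> "Cohort":
        return Cohort(records=list(self.records), label=label,
                      metadata=dict(self.metadata))


@dataclass
class EducationStrata:
    """Partition of a cohort into low / medium / high education bands.

    With the default cut points (6, 9): low is <=6 years of schooling,
    medium is 7-9 years, high is >=10 years.
    """

    boundaries: tuple[int, int]
    strata: Mapping[str, Cohort]

    LEVELS = ("low", "medium", "high")

    def sizes(self) -> dict[str, int]:
        return {name: len(c) for name, c in self.strata.items()}


def classify_education(education_years: int, boundaries: tuple[int, int] = (6, 9)) -> str:
    """Return the stratum name for a years-of-schooling value."""
    lower, upper = boundaries
    if education_years <= lower:
        return "low"
    if education_years <= upper:
        return "medium"
    return "high"


def stratify_by_education(cohort: Cohort,
                          boundaries: tuple[int, int] = (6, 9)) -> EducationStrata:
    """Partition a cohort into education strata at the given cut points.

    Every record lands in exactly one stratum; stratum sizes sum to the
    cohort size for any integer ``education_years >= 0``.
    """
    lower, upper = boundaries
    if not lower < upper:
        raise ValueError(f"boundaries must be strictly increasing, got {boundaries}")
    buckets: dict[str, list[SubjectRecord]] = {lvl: [] for lvl in EducationStrata.LEVELS}
    for rec in cohort:
        buckets[classify_education(rec.education_years, boundaries)].append(rec)
    strata = {
        name: Cohort(records=recs, label=f"{cohort.label}/{name}".lstrip("/"))
        for name, recs in buckets.items()
    }
    return EducationStrata(boundaries=tuple(boundaries), strata=strata)


def random_split(cohort: Cohort, seed: int,
                 stratify_on: EducationStrata | None = None) -> tuple[Cohort, Cohort]:
    """Split a cohort into disjoint groups A and B of near-equal size.

    Records are shuffled with a seeded generator and assigned alternately
    (A, B, A, ...); the alternation parity carries across strata, so sizes
    differ by at most one within every stratum AND overall, with A
    receiving the first surplus record.  The same seed always reproduces
    the same split.
    """
    if len(cohort) == 0:
        raise ValueError("cannot split an empty cohort")
    rng = np.random.default_rng(seed)
    if stratify_on is None:
        blocks: Sequence[Cohort] = [cohort]
    else:
        blocks = [stratify_on.strata[lvl] for lvl in EducationStrata.LEVELS]
    a_records: list[SubjectRecord] = []
    b_records: list[SubjectRecord] = []
    pos = 0
    for block in blocks:
        order = rng.permutation(len(block))
        for idx in order:
            rec = block.records[idx]
            if pos % 2 == 0:
                a_records.append(replace(rec, group="A"))
            else:
                b_records.append(replace(rec, group="B"))
            pos += 1
    group_a = Cohort(records=a_records, label=f"{cohort.label}/A".lstrip("/"))
    group_b = Cohort(records=b_records, label=f"{cohort.label}/B".lstrip("/"))
    return group_a, group_b


def read_cohort(path: str | Path, delimiter: str = ",", label: str | None = None) -> Cohort:
    """Read a cohort from delimited text with the standard header.

    Required columns: ``subject_id,age,sex,education_years,mmse,moca``;
    ``group`` is optional.  Row order is preserved.  Missing or extra
    required columns raise :class:`SchemaError`; out-of-range scores raise
    :class:`CohortValidationError` naming the offending row.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=delimiter, dtype={"subject_id": str}, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    extra = [c for c in frame.columns
             if c not in REQUIRED_COLUMNS + OPTIONAL_COLUMNS]
    if missing or extra:
        raise SchemaError(
            f"{path.name}: missing columns {missing or 'none'}, "
            f"unexpected columns {extra or 'none'}")
    records: list[SubjectRecord] = []
    for row_no, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            group = getattr(row, "group", None)
            if group is not None and (pd.isna(group) or str(group).strip() == ""):
                group = None
            records.append(SubjectRecord(
                subject_id=str(row.subject_id),
                age=float(row.age),
                sex=normalize_sex(row.sex),
                education_years=int(row.education_years),
                mmse=int(row.mmse),
                moca=int(row.moca),
                group=str(group) if group is not None else None,
            ))
        except CohortValidationError as err:
            raise CohortValidationError(f"{path.name} line {row_no}: {err}") from err
    return Cohort(records=records, label=label if label is not None else path.stem)


def write_cohort(cohort: Cohort, path: str | Path, delimiter: str = ",") -> None:
    """Write a cohort back to the same CSV schema read_cohort accepts."""
    cohort.to_frame().to_csv(path, sep=delimiter, index=False)


def cohort_from_arrays(mmse: Iterable[int], moca: Iterable[int], *,
                       education_years: Iterable[int] | None = None,
                       label: str = "") -> Cohort:
    """Convenience constructor from parallel score arrays (test/demo use)."""
    mmse = list(mmse)
    moca = list(moca)
    edu = list(education_years) if education_years is not None else [0] * len(mmse)
    records = [
        SubjectRecord(subject_id=f"s{i:04d}", age=70.0, sex="female",
                      education_years=int(e), mmse=int(m), moca=int(c))
        for i, (m, c, e) in enumerate(zip(mmse, moca, edu, strict=True))
    ]
    return Cohort(records=records, label=label)
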