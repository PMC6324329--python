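"""In-memory model and CSV interchange for minute-level activity cohorts.

A cohort pairs, per participant, a week of 1-minute accelerometer intensity
counts (ActiGraph "counts" units, 7 days x 1440 minutes, week starting
Monday 12:01 am) with six demographic attributes that together act as a
quasi-identifier: age, sex, educational level, annual household income,
race/ethnicity and country of birth.

The canonical on-disk form is a pair of CSV files:

* activity table, long format: ``record_id, day_index, minute_index,
  intensity`` with 1-based day (1 = Monday) and minute indices;
* demographics table, one row per record: ``record_id, age_years, sex,
  education, income, race_ethnicity, birth_country`` with missing values
  encoded as empty fields (allowed only for education, income and country
  of birth).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd

MINUTES_PER_DAY = 1440
DAYS_PER_WEEK = 7
WEEK_MINUTES = MINUTES_PER_DAY * DAYS_PER_WEEK  # 10 080

DAY_LABELS = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")
WEEKDAY_INDICES = (1, 2, 3, 4, 5)

SEX_CATEGORIES = ("male", "female")
EDUCATION_CATEGORIES = ("<=HS", ">HS")
INCOME_CATEGORIES = ("<25k", "25k-55k", ">55k")
RACE_CATEGORIES = ("Hispanic", "White", "Black", "Other")
BIRTH_CATEGORIES = ("US", "non-US")

#: attributes that may be missing before imputation
OPTIONAL_ATTRIBUTES = ("education", "income", "birth_country")

ACTIVITY_COLUMNS = ("record_id", "day_index", "minute_index", "intensity")
DEMOGRAPHIC_COLUMNS = (
    "record_id",
    "age_years",
    "sex",
    "education",
    "income",
    "race_ethnicity",
    "birth_country",
)


class SchemaError(ValueError):
    """Malformed table: unknown category, bad index, non-integer count."""


class LinkageError(ValueError):
    """Cross-table inconsistency: duplicate or orphan records."""


@dataclass(frozen=True)
class DemographicProfile:
    """The six quasi-identifier attributes of one participant.

    ``education``, ``income`` and ``birth_country`` may be ``None``
    (missing) before imputation; the remaining attributes are mandatory.
    """

    age_years: int
    sex: str
    education: Optional[str]
    income: Optional[str]
    race_ethnicity: str
    birth_country: Optional[str]

    def __post_init__(self) -> None:
        if not isinstance(self.age_years, (int, np.integer)) or self.age_years < 0:
            raise SchemaError(f"age_years must be a nonnegative integer, got {self.age_years!r}")
        _check_cat("sex", self.sex, SEX_CATEGORIES, optional=False)
        _check_cat("education", self.education, EDUCATION_CATEGORIES, optional=True)
        _check_cat("income", self.income, INCOME_CATEGORIES, optional=True)
        _check_cat("race_ethnicity", self.race_ethnicity, RACE_CATEGORIES, optional=False)
        _check_cat("birth_country", self.birth_country, BIRTH_CATEGORIES, optional=True)

    @property
    def is_imputed(self) -> bool:
        """True when no optional attribute is missing."""
        return None not in (self.education, self.income, self.birth_country)


def _check_cat(name: str, value, categories, *, optional: bool) -> None:
    if value is None:
        if optional:
            return
        raise SchemaError(f"{name} may not be missing")
    if value not in categories:
        raise SchemaError(f"unknown {name} category {value!r}; expected one of {categories}")


@dataclass
class MinuteSeries:
    """One participant's minute-resolution intensity counts.

    ``counts`` has shape ``(n_days, 1440)`` with nonnegative integer
    entries; ``day_indices`` are the 1-based days of week actually
    recorded (1 = Monday). A complete week covers days 1..7.
    """

    record_id: str
    counts: np.ndarray
    day_indices: tuple[int, ...] = tuple(range(1, DAYS_PER_WEEK + 1))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim == 1:
            if self.counts.size % MINUTES_PER_DAY:
                raise SchemaError(
                    f"record {self.record_id}: series length {self.counts.size} "
                    f"is not a multiple of {MINUTES_PER_DAY}"
                )
            self.counts = self.counts.reshape(-1, MINUTES_PER_DAY)
        if self.counts.shape[1] != MINUTES_PER_DAY:
            raise SchemaError(
                f"record {self.record_id}: day width {self.counts.shape[1]} != {MINUTES_PER_DAY}"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise SchemaError(f"record {self.record_id}: non-integer intensity values")
            self.counts = self.counts.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise SchemaError(f"record {self.record_id}: negative intensity values")
        self.day_indices = tuple(int(d) for d in self.day_indices)
        if len(self.day_indices) != self.counts.shape[0]:
            raise SchemaError(
                f"record {self.record_id}: {len(self.day_indices)} day indices for "
                f"{self.counts.shape[0]} recorded days"
            )
        if any(d < 1 or d > DAYS_PER_WEEK for d in self.day_indices):
            raise SchemaError(f"record {self.record_id}: day index outside 1..7")
        if len(set(self.day_indices)) != len(self.day_indices):
            raise SchemaError(f"record {self.record_id}: duplicate day index")

    @property
    def start_day(self) -> str:
        return DAY_LABELS[0]

    @property
    def is_complete(self) -> bool:
        """Whether the full 7-day week (10 080 minutes) was recorded."""
        return self.day_indices == tuple(range(1, DAYS_PER_WEEK + 1))

    def day(self, day_index: int) -> np.ndarray:
        """The 1440-minute vector of one recorded day (1 = Monday)."""
        try:
            pos = self.day_indices.index(day_index)
        except ValueError:
            raise KeyError(f"record {self.record_id}: day {day_index} not recorded") from None
        return self.counts[pos]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, MinuteSeries)
            and self.record_id == other.record_id
            and self.day_indices == other.day_indices
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class Cohort:
    """A keyed collection of (demographics, minute series) pairs."""

    participants: dict[str, tuple[DemographicProfile, MinuteSeries]] = field(default_factory=dict)
    population_label: str = "mixed"

    def __post_init__(self) -> None:
        if self.population_label not in ("adult", "child", "mixed"):
            raise SchemaError(f"unknown population label {self.population_label!r}")
        for rid, (profile, series) in self.participants.items():
            if series.record_id != rid:
                raise LinkageError(f"series record_id {series.record_id!r} keyed under {rid!r}")
            if self.population_label == "adult" and profile.age_years < 18:
                raise SchemaError(f"record {rid}: age {profile.age_years} in adult cohort")
            if self.population_label == "child" and profile.age_years >= 18:
                raise SchemaError(f"record {rid}: age {profile.age_years} in child cohort")

    def __len__(self) -> int:
        return len(self.participants)

    def __iter__(self) -> Iterator[str]:
        return iter(self.record_ids)

    def __contains__(self, record_id: str) -> bool:
        return record_id in self.participants

    @property
    def record_ids(self) -> list[str]:
        return sorted(self.participants)

    def profile(self, record_id: str) -> DemographicProfile:
        return self.participants[record_id][0]

    def series(self, record_id: str) -> MinuteSeries:
        return self.participants[record_id][1]

    def profiles(self) -> dict[str, DemographicProfile]:
        return {rid: self.profile(rid) for rid in self.record_ids}

    def subset(self, record_ids, population_label: str | None = None) -> "Cohort":
        """A new cohort restricted to ``record_ids`` (order-insensitive)."""
        keep = set(record_ids)
        missing = keep - set(self.participants)
        if missing:
            raise LinkageError(f"unknown record ids: {sorted(missing)}")
        return Cohort(
            {rid: self.participants[rid] for rid in self.participants if rid in keep},
            population_label or self.population_label,
        )

    def with_series(self, series_map: dict[str, MinuteSeries]) -> "Cohort":
        """A new cohort with some records' series replaced."""
        parts = dict(self.participants)
        for rid, series in series_map.items():
            parts[rid] = (parts[rid][0], series)
        return Cohort(parts, self.population_label)

    def with_profiles(self, profile_map: dict[str, DemographicProfile]) -> "Cohort":
        parts = dict(self.participants)
        for rid, profile in profile_map.items():
            parts[rid] = (profile, parts[rid][1])
        return Cohort(parts, self.population_label)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Cohort)
            and self.population_label == other.population_label
            and set(self.participants) == set(other.participants)
            and all(
                self.profile(r) == other.profile(r) and self.series(r) == other.series(r)
                for r in self.participants
            )
        )


def read_cohort(
    activity_path: str | Path,
    demographics_path: str | Path,
    population_label: str | None = None,
) -> Cohort:
    """Read a cohort from the canonical CSV pair.

    With ``population_label=None`` the label is inferred from the ages
    (adult if all >= 18 y, child if all < 18 y, else mixed), so writing
    and re-reading a cohort reproduces it exactly. Raises
    :class:`SchemaError` for unknown categories, bad indices or
    non-integer/negative intensities (naming the offending row), and
    :class:`LinkageError` for duplicate measurements or activity records
    absent from the demographics table. Partially recorded days are a
    schema error; wholly absent days mark the record incomplete.
    """
    demo = pd.read_csv(demographics_path, dtype=str, keep_default_na=False)
    _require_columns(demo, DEMOGRAPHIC_COLUMNS, "demographics")
    if demo["record_id"].duplicated().any():
        dup = demo.loc[demo["record_id"].duplicated(), "record_id"].iloc[0]
        raise LinkageError(f"duplicate demographics row for record {dup!r}")

    profiles: dict[str, DemographicProfile] = {}
    for row in demo.itertuples(index=True):
        try:
            age = int(row.age_years)
        except ValueError:
            raise SchemaError(
                f"demographics row {row.Index}: non-integer age {row.age_years!r}"
            ) from None
        try:
            profiles[row.record_id] = DemographicProfile(
                age_years=age,
                sex=row.sex,
                education=row.education or None,
                income=row.income or None,
                race_ethnicity=row.race_ethnicity,
                birth_country=row.birth_country or None,
            )
        except SchemaError as exc:
            raise SchemaError(f"demographics row {row.Index}: {exc}") from None

    act = pd.read_csv(activity_path, dtype={"record_id": str})
    _require_columns(act, ACTIVITY_COLUMNS, "activity")

    if len(act):
        for col in ("day_index", "minute_index", "intensity"):
            vals = pd.to_numeric(act[col], errors="coerce")
            bad = vals.isna() | (np.mod(vals, 1) != 0)
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise SchemaError(f"activity row {i}: non-integer {col} {act[col].iloc[i]!r}")
            act[col] = vals.astype(np.int64)
        if (act["intensity"] < 0).any():
            i = int(np.flatnonzero(act["intensity"] < 0)[0])
            raise SchemaError(f"activity row {i}: negative intensity")
        if not act["day_index"].between(1, DAYS_PER_WEEK).all():
            raise SchemaError("activity day_index outside 1..7")
        if not act["minute_index"].between(1, MINUTES_PER_DAY).all():
            raise SchemaError("activity minute_index outside 1..1440")
        dup = act.duplicated(subset=["record_id", "day_index", "minute_index"])
        if dup.any():
            r = act.loc[dup].iloc[0]
            raise LinkageError(
                f"duplicate measurement for record {r.record_id!r}, "
                f"day {r.day_index}, minute {r.minute_index}"
            )
        orphans = set(act["record_id"]) - set(profiles)
        if orphans:
            raise LinkageError(f"activity records absent from demographics: {sorted(orphans)[:5]}")

    participants: dict[str, tuple[DemographicProfile, MinuteSeries]] = {}
    for rid, g in act.groupby("record_id", sort=True):
        days = []
        mats = []
        for day, dg in g.groupby("day_index", sort=True):
            if len(dg) != MINUTES_PER_DAY:
                raise SchemaError(
                    f"record {rid!r} day {day}: {len(dg)} minutes recorded "
                    f"(expected {MINUTES_PER_DAY} or none)"
                )
            vec = np.zeros(MINUTES_PER_DAY, dtype=np.int64)
            vec[dg["minute_index"].to_numpy() - 1] = dg["intensity"].to_numpy()
            days.append(int(day))
            mats.append(vec)
        participants[rid] = (
            profiles[rid],
            MinuteSeries(rid, np.vstack(mats), tuple(days)),
        )
    # demographics-only records (no activity rows) are dropped: a cohort
    # participant is defined by having worn the monitor
    if population_label is None:
        ages = [p.age_years for p, _ in participants.values()]
        if ages and all(a >= 18 for a in ages):
            population_label = "adult"
        elif ages and all(a < 18 for a in ages):
            population_label = "child"
        else:
            population_label = "mixed"
    return Cohort(participants, population_label)


def write_cohort(
    cohort: Cohort,
    activity_path: str | Path,
    demographics_path: str | Path,
) -> None:
    """Write a cohort to the canonical CSV pair (round-trip exact)."""
    demo_rows = []
    act_frames = []
    for rid in cohort.record_ids:
        p = cohort.profile(rid)
        demo_rows.append(
            {
                "record_id": rid,
                "age_years": p.age_years,
                "sex": p.sex,
                "education": p.education or "",
                "income": p.income or "",
                "race_ethnicity": p.race_ethnicity,
                "birth_country": p.birth_country or "",
            }
        )
        s = cohort.series(rid)
        n_days = len(s.day_indices)
        act_frames.append(
            pd.DataFrame(
                {
                    "record_id": rid,
                    "day_index": np.repeat(np.array(s.day_indices, dtype=np.int64), MINUTES_PER_DAY),
                    "minute_index": np.tile(
                        np.arange(1, MINUTES_PER_DAY + 1, dtype=np.int64), n_days
                    ),
                    "intensity": s.counts.ravel(),
                }
            )
        )
    pd.DataFrame(demo_rows, columns=list(DEMOGRAPHIC_COLUMNS)).to_csv(
        demographics_path, index=False
    )
    if act_frames:
        pd.concat(act_frames, ignore_index=True).to_csv(activity_path, index=False)
    else:
        pd.DataFrame(columns=list(ACTIVITY_COLUMNS)).to_csv(activity_path, index=False)


def _require_columns(df: pd.DataFrame, columns, which: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{which} table missing columns {missing}")
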