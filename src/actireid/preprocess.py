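"""Data preparation: exclusions, imputation, population split, weekday
selection, partial temporal aggregation and train/test construction.

The pipeline mirrors the preparation applied to national accelerometer
survey data before the matching attack: records with an incomplete week
or a constant (zero-variance) intensity series are removed, missing
education/income/birth-country entries are imputed by the rounded mean
of the valid coded values, the cohort is split into adults (>= 18 y) and
children, weekend days are dropped, and each weekday's 1440 minute
counts are summed into k-minute windows. Training and testing tables
hold one row per (record, day) so that both live in the same
1440/k-dimensional feature space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    MINUTES_PER_DAY,
    WEEKDAY_INDICES,
    Cohort,
    DemographicProfile,
    MinuteSeries,
)

#: the aggregation grid studied, in minutes (any divisor of 1440 is accepted)
STANDARD_INTERVALS = (15, 20, 30, 60, 120, 240, 360, 480, 720, 1440)

EDUCATION_CODES = {"<=HS": 1, ">HS": 2}
INCOME_CODES = {"<25k": 1, "25k-55k": 2, ">55k": 3}
BIRTH_CODES = {"US": 1, "non-US": 2}

DEFAULT_TRAIN_DAYS = (1, 2, 3)  # Mon, Tue, Wed
DEFAULT_TEST_DAYS = (4, 5)  # Thu, Fri


class ImputationError(ValueError):
    """An attribute has no valid values to impute from."""


def apply_exclusions(cohort: Cohort) -> tuple[Cohort, dict[str, int]]:
    """Drop incomplete-week and zero-variance records.

    Zero variance is judged on the full recorded 7-day minute series
    (before weekday selection); an incomplete record is counted as
    incomplete even if also constant. Returns the filtered cohort and a
    log of exclusion counts per reason.
    """
    log = {"incomplete": 0, "zero_variance": 0}
    keep = []
    for rid in cohort.record_ids:
        series = cohort.series(rid)
        if not series.is_complete:
            log["incomplete"] += 1
        elif np.all(series.counts == series.counts.flat[0]):
            log["zero_variance"] += 1
        else:
            keep.append(rid)
    return cohort.subset(keep), log


def select_weekdays(cohort: Cohort) -> Cohort:
    """Restrict every series to Monday-Friday (idempotent)."""
    replacements = {}
    for rid in cohort.record_ids:
        s = cohort.series(rid)
        keep = [i for i, d in enumerate(s.day_indices) if d in WEEKDAY_INDICES]
        if len(keep) == len(s.day_indices):
            continue
        replacements[rid] = MinuteSeries(
            rid, s.counts[keep], tuple(s.day_indices[i] for i in keep)
        )
    return cohort.with_series(replacements) if replacements else cohort


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _impute_coded(values: list[int | None], attr: str) -> int:
    valid = [v for v in values if v is not None]
    if not valid:
        raise ImputationError(f"no valid values to impute {attr!r} from")
    return _round_half_up(sum(valid) / len(valid))


def impute_demographics(
    profiles: dict[str, DemographicProfile] | Sequence[DemographicProfile],
) -> dict[str, DemographicProfile] | list[DemographicProfile]:
    """Replace missing education/income/birth-country entries by the
    rounded mean of the valid coded values (round half up).

    Codes: education 1-2, income 1-3, birth country 1-2. Computed over
    the profiles given, so callers control the pooling (per population,
    per dataset). Non-missing values are never altered.
    """
    as_dict = isinstance(profiles, dict)
    items = list(profiles.items()) if as_dict else list(enumerate(profiles))
    specs = [
        ("education", EDUCATION_CODES),
        ("income", INCOME_CODES),
        ("birth_country", BIRTH_CODES),
    ]
    fills = {}
    for attr, codes in specs:
        values = [
            codes[getattr(p, attr)] if getattr(p, attr) is not None else None
            for _, p in items
        ]
        if any(v is None for v in values):
            code = _impute_coded(values, attr)
            fills[attr] = {v: k for k, v in codes.items()}[code]

    out = []
    for key, p in items:
        updates = {
            attr: fills[attr]
            for attr in fills
            if getattr(p, attr) is None
        }
        out.append((key, DemographicProfile(**{**p.__dict__, **updates}) if updates else p))
    return dict(out) if as_dict else [p for _, p in out]


def split_population(cohort: Cohort) -> tuple[Cohort, Cohort]:
    """Partition into adults (age >= 18) and children (age < 18)."""
    adult_ids = [r for r in cohort.record_ids if cohort.profile(r).age_years >= 18]
    child_ids = [r for r in cohort.record_ids if cohort.profile(r).age_years < 18]
    return (
        cohort.subset(adult_ids, population_label="adult"),
        cohort.subset(child_ids, population_label="child"),
    )


def recategorize_child_education(grade_code: int) -> str:
    """Map a child-scheme educational code (highest grade completed,
    0-12, 13+ for any post-secondary) onto the adult two-level scheme;
    used when 18-19-year-olds were coded on the child scheme. Any
    pre-college code maps to '<=HS'."""
    return "<=HS" if grade_code <= 12 else ">HS"


def aggregate_intervals(cohort: Cohort, k: int) -> pd.DataFrame:
    """Sum each day's minute counts into k-minute windows.

    Windows are left-aligned and non-overlapping: window ``j`` covers
    minutes ``jk+1 .. (j+1)k``. Returns a tidy frame with columns
    ``record_id, day_index, w000..`` (1440/k window sums per row); the
    row sum equals the day's minute sum exactly.
    """
    if k <= 0 or MINUTES_PER_DAY % k:
        raise ValueError(f"interval width {k} does not divide {MINUTES_PER_DAY}")
    m = MINUTES_PER_DAY // k
    cols = [f"w{j:03d}" for j in range(m)]
    rows = []
    index = []
    for rid in cohort.record_ids:
        s = cohort.series(rid)
        agg = s.counts.reshape(len(s.day_indices), m, k).sum(axis=2)
        for pos, day in enumerate(s.day_indices):
            index.append((rid, day))
            rows.append(agg[pos])
    df = pd.DataFrame(rows, columns=cols, dtype=np.int64)
    meta = pd.DataFrame(index, columns=["record_id", "day_index"])
    return pd.concat([meta, df], axis=1)


@dataclass
class FeatureTable:
    """Per-(record, day) aggregated activity vectors for one role.

    ``table`` has columns ``record_id, day_index, w000..`` with
    ``1440/interval_minutes`` feature columns; every row's day index
    belongs to ``day_set``.
    """

    interval_minutes: int
    role: str  # training | testing | calibration
    day_set: tuple[int, ...]
    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        m = MINUTES_PER_DAY // self.interval_minutes
        if MINUTES_PER_DAY % self.interval_minutes:
            raise ValueError(f"interval width {self.interval_minutes} does not divide 1440")
        if len(self.feature_columns) != m:
            raise ValueError(
                f"expected {m} feature columns for k={self.interval_minutes}, "
                f"found {len(self.feature_columns)}"
            )
        if len(self.table) and not self.table["day_index"].isin(self.day_set).all():
            raise ValueError("rows outside the declared day set")

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.table.columns if c.startswith("w")]

    @property
    def record_ids(self) -> list[str]:
        return sorted(self.table["record_id"].unique())

    def rows_for(self, record_id: str) -> np.ndarray:
        """Feature matrix (n_days x m) of one record, days ascending."""
        sub = self.table[self.table["record_id"] == record_id].sort_values("day_index")
        return sub[self.feature_columns].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        header = (
            f"# interval_minutes={self.interval_minutes} role={self.role} "
            f"day_set={','.join(map(str, self.day_set))}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            self.table.to_csv(fh, index=False)


def build_split(
    aggregated: pd.DataFrame,
    k: int,
    train_days: Iterable[int] = DEFAULT_TRAIN_DAYS,
    test_days: Iterable[int] = DEFAULT_TEST_DAYS,
) -> tuple[FeatureTable, FeatureTable]:
    """Split an aggregated table into disjoint training/testing day sets."""
    train_days = tuple(sorted(train_days))
    test_days = tuple(sorted(test_days))
    overlap = set(train_days) & set(test_days)
    if overlap:
        raise ValueError(f"train/test day sets overlap: {sorted(overlap)}")
    for d in train_days + test_days:
        if d not in WEEKDAY_INDICES:
            raise ValueError(f"day index {d} is not a weekday (1..5)")
    train = aggregated[aggregated["day_index"].isin(train_days)].reset_index(drop=True)
    test = aggregated[aggregated["day_index"].isin(test_days)].reset_index(drop=True)
    return (
        FeatureTable(k, "training", train_days, train),
        FeatureTable(k, "testing", test_days, test),
    )


def prepare_cohort(cohort: Cohort) -> tuple[Cohort, dict[str, int]]:
    """Exclusions -> weekday selection -> imputation, in the standard
    order (exclusions judge the full recorded week)."""
    filtered, log = apply_exclusions(cohort)
    weekdays = select_weekdays(filtered)
    imputed = weekdays.with_profiles(impute_demographics(weekdays.profiles()))
    return imputed, log


def prepare_features(
    cohort: Cohort,
    k: int,
    train_days: Iterable[int] = DEFAULT_TRAIN_DAYS,
    test_days: Iterable[int] = DEFAULT_TEST_DAYS,
) -> tuple[FeatureTable, FeatureTable]:
    """Aggregate a prepared cohort at width ``k`` and split by day."""
    return build_split(aggregate_intervals(cohort, k), k, train_days, test_days)
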