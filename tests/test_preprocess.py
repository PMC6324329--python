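"""Exclusions, weekday selection, imputation, population split,
aggregation and train/test construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from actireid.cohort import Cohort, MinuteSeries
from actireid.preprocess import (
    DEFAULT_TEST_DAYS,
    DEFAULT_TRAIN_DAYS,
    ImputationError,
    STANDARD_INTERVALS,
    aggregate_intervals,
    apply_exclusions,
    build_split,
    impute_demographics,
    recategorize_child_education,
    select_weekdays,
    split_population,
)
from actireid.simulate import GeneratorConfig, generate_cohort

from conftest import make_cohort, make_profile, make_series


class TestExclusions:
    def test_constant_record_excluded(self):
        cohort = make_cohort(n=10)
        flat = MinuteSeries("r0000", np.zeros((7, 1440), dtype=np.int64))
        cohort = cohort.with_series({"r0000": flat})
        kept, log = apply_exclusions(cohort)
        assert len(kept) == 9 and "r0000" not in kept
        assert log == {"incomplete": 0, "zero_variance": 1}

    def test_six_day_record_excluded_as_incomplete(self):
        cohort = make_cohort(n=3)
        cohort = cohort.with_series({"r0001": make_series("r0001", n_days=6)})
        kept, log = apply_exclusions(cohort)
        assert log["incomplete"] == 1 and "r0001" not in kept

    def test_retained_count_matches_injected_defects(self):
        cohort = generate_cohort(GeneratorConfig(n=100, seed=3, defect_rates=(0.1, 0.05)))
        kept, log = apply_exclusions(cohort)
        assert len(kept) == 100 - 10 - 5
        assert log == {"incomplete": 10, "zero_variance": 5}


class TestSelectWeekdays:
    def test_five_days_retained(self):
        cohort = select_weekdays(make_cohort(n=2))
        s = cohort.series("r0000")
        assert s.counts.shape == (5, 1440) and s.day_indices == (1, 2, 3, 4, 5)

    def test_weekend_only_activity_yields_zero_weekdays(self):
        counts = np.zeros((7, 1440), dtype=np.int64)
        counts[5:] = 100  # Sat, Sun only
        cohort = Cohort({"x": (make_profile(), MinuteSeries("x", counts))})
        kept, log = apply_exclusions(cohort)  # not constant over the full week
        assert len(kept) == 1
        wk = select_weekdays(kept)
        assert wk.series("x").counts.sum() == 0

    def test_idempotent(self):
        once = select_weekdays(make_cohort(n=2))
        assert select_weekdays(once) == once


class TestImputation:
    def test_no_missing_unchanged(self):
        profiles = [make_profile(), make_profile(sex="female")]
        assert impute_demographics(profiles) == profiles

    def test_income_rounded_mean(self):
        # valid codes {1,2,2}: mean 5/3 -> 2 -> '25k-55k'
        profiles = [
            make_profile(income="<25k"),
            make_profile(income="25k-55k"),
            make_profile(income="25k-55k"),
            make_profile(income=None),
        ]
        out = impute_demographics(profiles)
        assert out[3].income == "25k-55k"

    def test_round_half_up_tie(self):
        # valid codes {1,2}: mean 1.5 rounds up to 2
        profiles = [
            make_profile(income="<25k"),
            make_profile(income=">55k", education="<=HS"),
            make_profile(income=None),
        ]
        # income codes {1,3}: mean 2 -> '25k-55k'; education tie case below
        assert impute_demographics(profiles)[2].income == "25k-55k"
        profiles = [
            make_profile(education="<=HS"),
            make_profile(education=">HS"),
            make_profile(education=None),
        ]
        assert impute_demographics(profiles)[2].education == ">HS"

    def test_never_alters_non_missing(self):
        profiles = [make_profile(income="<25k"), make_profile(income=None)]
        out = impute_demographics(profiles)
        assert out[0] == profiles[0]

    def test_all_missing_raises(self):
        profiles = [make_profile(income=None), make_profile(income=None)]
        with pytest.raises(ImputationError):
            impute_demographics(profiles)

    def test_dict_form_preserves_keys(self):
        profiles = {"a": make_profile(income=None), "b": make_profile()}
        out = impute_demographics(profiles)
        assert set(out) == {"a", "b"} and out["a"].income is not None


class TestSplitPopulation:
    def test_age_boundary(self):
        cohort = Cohort(
            {
                "a": (make_profile(age_years=17), make_series("a")),
                "b": (make_profile(age_years=18), make_series("b")),
            }
        )
        adults, children = split_population(cohort)
        assert adults.record_ids == ["b"] and children.record_ids == ["a"]
        assert adults.population_label == "adult"

    def test_empty_cohort(self):
        adults, children = split_population(Cohort({}))
        assert len(adults) == len(children) == 0

    def test_partition_is_disjoint_and_complete(self):
        cohort = generate_cohort(GeneratorConfig(n=20, seed=0))
        adults, children = split_population(cohort)
        assert len(adults) + len(children) == 20
        assert not set(adults.record_ids) & set(children.record_ids)

    def test_child_education_recategorization(self):
        assert recategorize_child_education(11) == "<=HS"
        assert recategorize_child_education(12) == "<=HS"
        assert recategorize_child_education(13) == ">HS"


class TestAggregation:
    def test_twenty_minutes_gives_72_windows(self):
        agg = aggregate_intervals(select_weekdays(make_cohort(n=1)), 20)
        assert agg.shape == (5, 2 + 72)

    def test_full_day_arithmetic_series(self):
        counts = np.tile(np.arange(1, 1441, dtype=np.int64), (7, 1))
        cohort = Cohort({"x": (make_profile(), MinuteSeries("x", counts))})
        agg = aggregate_intervals(cohort, 1440)
        assert (agg["w000"] == 1440 * 1441 // 2).all()

    @pytest.mark.parametrize("k", STANDARD_INTERVALS)
    def test_mass_conservation(self, k):
        cohort = make_cohort(n=2)
        agg = aggregate_intervals(cohort, k)
        wcols = [c for c in agg.columns if c.startswith("w")]
        for rid in cohort.record_ids:
            s = cohort.series(rid)
            daily = agg[agg["record_id"] == rid].sort_values("day_index")[wcols].sum(axis=1)
            assert np.array_equal(daily.to_numpy(), s.counts.sum(axis=1))

    def test_non_divisor_rejected(self):
        with pytest.raises(ValueError):
            aggregate_intervals(make_cohort(n=1), 7)

    @settings(max_examples=20, deadline=None)
    @given(st.sampled_from([15, 20, 30, 60, 120, 240, 360, 480, 720, 1440]),
           st.integers(0, 2**16))
    def test_window_sums_match_manual_reshape(self, k, seed):
        cohort = make_cohort(n=1, seed=seed)
        agg = aggregate_intervals(cohort, k)
        wcols = [c for c in agg.columns if c.startswith("w")]
        manual = cohort.series("r0000").counts.reshape(7, 1440 // k, k).sum(axis=2)
        assert np.array_equal(agg[wcols].to_numpy(), manual)


class TestBuildSplit:
    def test_default_split_row_counts(self):
        cohort = select_weekdays(make_cohort(n=4))
        train, test = build_split(aggregate_intervals(cohort, 20), 20)
        assert len(train.table) == 3 * 4 and len(test.table) == 2 * 4
        assert train.day_set == DEFAULT_TRAIN_DAYS and test.day_set == DEFAULT_TEST_DAYS

    def test_alternative_split(self):
        cohort = select_weekdays(make_cohort(n=4))
        train, test = build_split(aggregate_intervals(cohort, 20), 20, (1, 2, 3, 5), (4,))
        assert len(train.table) == 16 and len(test.table) == 4

    def test_overlapping_days_rejected(self):
        cohort = select_weekdays(make_cohort(n=2))
        with pytest.raises(ValueError, match="overlap"):
            build_split(aggregate_intervals(cohort, 20), 20, (1, 2, 3), (3, 4))
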