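"""Blocking, per-block matchers, prediction routing, tie-breaks and
abstention calibration."""

import numpy as np
import pytest

from actireid.attack import (
    ABSTENTION_GRID,
    NO_MATCH,
    AttackPrediction,
    apply_abstention,
    block_key,
    build_blocks,
    calibrate_abstention,
    fit_blocked_model,
    predict_record,
    run_attack,
    train_block_matcher,
)
from actireid.preprocess import prepare_cohort, prepare_features
from actireid.simulate import (
    GeneratorConfig,
    generate_cohort,
    identical_demographics_config,
)

from conftest import make_profile


def noiseless_cohort(n, seed=0, **overrides):
    cfg = GeneratorConfig(
        n=n, seed=seed, day_noise_scale=0.0, sleep_jitter_minutes=0.0, **overrides
    )
    cohort, _ = prepare_cohort(generate_cohort(cfg))
    return cohort


def nearest_centroid_predictions(train, test):
    """Independent oracle: per-record training centroid, averaged test
    rows, 1-nearest-neighbour in Euclidean distance (ties lowest id)."""
    ids = train.record_ids
    centroids = np.vstack([train.rows_for(r).mean(axis=0) for r in ids])
    out = {}
    for rid in test.record_ids:
        q = test.rows_for(rid).mean(axis=0)
        d = np.linalg.norm(centroids - q, axis=1)
        out[rid] = ids[int(np.argmin(d))]  # ids sorted: first min = lowest id
    return out


class TestBlocking:
    def test_all_distinct_demographics_singletons(self):
        profiles = {f"r{i}": make_profile(age_years=30 + i) for i in range(5)}
        blocks = build_blocks(profiles.keys(), profiles, "full")
        assert len(blocks) == 5 and all(len(v) == 1 for v in blocks.values())

    def test_identical_demographics_one_block(self):
        profiles = {f"r{i}": make_profile() for i in range(4)}
        blocks = build_blocks(profiles.keys(), profiles, "full")
        assert len(blocks) == 1 and len(next(iter(blocks.values()))) == 4

    def test_blocking_none_single_block(self):
        profiles = {"a": make_profile(age_years=20), "b": make_profile(age_years=70)}
        assert len(build_blocks(profiles.keys(), profiles, "none")) == 1

    def test_age_sex_key(self):
        assert block_key(make_profile(), "age_sex") == (40, "male")

    def test_age_binning(self):
        assert block_key(make_profile(age_years=43), "full", age_bin_years=10)[0] == 4

    def test_unimputed_profile_rejected(self):
        with pytest.raises(ValueError, match="imputed"):
            block_key(make_profile(income=None), "full")


class TestBlockMatchers:
    def test_singleton_block_constant_matcher(self):
        m = train_block_matcher(
            np.zeros((3, 4)), np.array(["a", "a", "a"]), np.array([1, 2, 3]), "rf"
        )
        assert m.estimator is None and m.members == ["a"]

    @pytest.mark.parametrize("mode", ["svm", "rf"])
    def test_two_record_separable_block(self, mode):
        # distinct constant signatures, three days each: leave-one-day-out
        # must be perfect and the final matcher must separate them
        X = np.vstack([np.tile([10.0, 0.0, 5.0, 1.0], (3, 1)),
                       np.tile([0.0, 12.0, 1.0, 7.0], (3, 1))])
        y = np.array(["a"] * 3 + ["b"] * 3)
        days = np.array([1, 2, 3, 1, 2, 3])
        m = train_block_matcher(X, y, days, mode, seed=0)
        scores = m.day_scores(np.array([[10.0, 0.0, 5.0, 1.0]]))
        assert m.members[int(np.argmax(scores[0]))] == "a"

    @pytest.mark.parametrize("mode", ["svm", "rf"])
    def test_duplicate_series_confusion_confined(self, mode):
        # records a and b identical, c distinct: held-out day of c is always
        # classified c; a duplicated day goes to a or b, never c
        dup = np.tile([5.0, 5.0, 0.0, 0.0], (3, 1))
        distinct = np.tile([0.0, 0.0, 9.0, 9.0], (3, 1))
        X = np.vstack([dup, dup, distinct])
        y = np.array(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        days = np.tile([1, 2, 3], 3)
        m = train_block_matcher(X, y, days, mode, seed=0)
        c_pred = m.members[int(np.argmax(m.day_scores(distinct[:1])[0]))]
        assert c_pred == "c"
        dup_pred = m.members[int(np.argmax(m.day_scores(dup[:1])[0]))]
        assert dup_pred in ("a", "b")


class TestPredictRouting:
    def test_unseen_block_key_no_match(self):
        cohort = noiseless_cohort(5)
        profiles = cohort.profiles()
        train, test = prepare_features(cohort, 20)
        model = fit_blocked_model(train, profiles, "rf", "full", seed=0)
        stranger = make_profile(age_years=83, race_ethnicity="Other", income=">55k")
        pred = predict_record(model, test.rows_for(test.record_ids[0]), stranger)
        assert pred.record_id == NO_MATCH and pred.confidence == 1.0

    def test_demographics_only_tie_break_lowest_id(self):
        cohort = noiseless_cohort(6)
        profiles = {r: make_profile() for r in cohort.record_ids}  # one block
        train, test = prepare_features(cohort, 20)
        preds = run_attack(train, test, profiles, "demographics_only", "full")
        lowest = min(cohort.record_ids)
        assert all(p.record_id == lowest for p in preds.values())
        assert all(np.isclose(p.confidence, 1 / 6) for p in preds.values())

    def test_feature_length_mismatch_rejected(self):
        cohort = noiseless_cohort(3)
        profiles = cohort.profiles()
        train, _ = prepare_features(cohort, 20)
        model = fit_blocked_model(train, profiles, "rf", "full", seed=0)
        with pytest.raises(ValueError, match="feature length"):
            predict_record(model, np.zeros((2, 10)), profiles[cohort.record_ids[0]])

    def test_train_test_day_overlap_rejected(self):
        cohort = noiseless_cohort(3)
        train, _ = prepare_features(cohort, 20)
        with pytest.raises(ValueError, match="overlap"):
            run_attack(train, train, cohort.profiles(), "rf", "full")


class TestNoiselessOracleEquivalence:
    """On noiseless cohorts the attack must match a nearest-centroid
    1-NN oracle record for record, at 100% accuracy."""

    @pytest.mark.parametrize("mode,blocking", [("svm", "none"), ("rf", "none"), ("rf", "full")])
    def test_agreement_with_oracle(self, mode, blocking):
        cohort = noiseless_cohort(12, seed=4)
        profiles = cohort.profiles()
        train, test = prepare_features(cohort, 20)
        preds = run_attack(train, test, profiles, mode, blocking, seed=0)
        oracle = nearest_centroid_predictions(train, test)
        for rid in test.record_ids:
            assert preds[rid].record_id == oracle[rid] == rid


class TestChanceLevel:
    def test_no_signal_accuracy_near_chance(self):
        # s=0, identical demographics: matching cannot beat 1/n
        accs = []
        for seed in range(5):
            cohort, _ = prepare_cohort(
                generate_cohort(identical_demographics_config(20, seed=seed, signature_strength=0.0))
            )
            train, test = prepare_features(cohort, 20)
            preds = run_attack(train, test, cohort.profiles(), "rf", "full", seed=seed)
            accs.append(np.mean([p.record_id == r for r, p in preds.items()]))
        p = 1 / 20
        se = np.sqrt(p * (1 - p) / (5 * 20))
        assert abs(np.mean(accs) - p) < 3 * se


class TestAbstention:
    def test_tau_zero_never_abstains(self):
        pred = AttackPrediction("a", 0.01)
        assert apply_abstention(pred, 0.0) is pred

    def test_tau_above_one_always_abstains(self):
        assert apply_abstention(AttackPrediction("a", 1.0), 1.01).record_id == NO_MATCH

    def test_calibration_attains_grid_maximum(self):
        # exhaustive grid oracle: recompute accuracy at every grid point
        rng = np.random.default_rng(0)
        known = {f"k{i}" for i in range(30)}
        preds = {}
        for i in range(30):  # known: mostly correct, high confidence
            correct = rng.random() < 0.8
            preds[f"k{i}"] = AttackPrediction(
                f"k{i}" if correct else "k999", float(rng.uniform(0.4, 1.0))
            )
        for i in range(10):  # absent records: low confidence named guesses
            preds[f"u{i}"] = AttackPrediction("k0", float(rng.uniform(0.0, 0.5)))
        tau = calibrate_abstention(preds, known)

        def acc(t):
            c = 0
            for rid, p in preds.items():
                q = apply_abstention(p, t)
                c += (q.record_id == rid) if rid in known else (q.record_id == NO_MATCH)
            return c / len(preds)

        grid_best = max(acc(t) for t in ABSTENTION_GRID)
        assert acc(tau) == grid_best

    def test_empty_calibration_rejected(self):
        with pytest.raises(ValueError):
            calibrate_abstention({}, set())


class TestDemographicsOnlyIdentity:
    def test_accuracy_equals_direct_block_count(self):
        # exact identity: correct = singleton self-matches + lowest-id wins
        cohort, _ = prepare_cohort(generate_cohort(GeneratorConfig(n=40, seed=9)))
        profiles = cohort.profiles()
        train, test = prepare_features(cohort, 20)
        preds = run_attack(train, test, profiles, "demographics_only", "full")
        n_correct = sum(p.record_id == r for r, p in preds.items())
        blocks = build_blocks(train.record_ids, profiles, "full")
        expected = sum(1 for members in blocks.values() for m in [min(members)]
                       if m in test.record_ids)
        assert n_correct == expected
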