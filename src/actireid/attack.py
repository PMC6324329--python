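"""The reidentification attack: demographic blocking plus per-block
multiclass matching of aggregated activity day-vectors.

Records are first partitioned by their demographic combination (the
blocking key); within each block a multiclass classifier is trained with
the record identifier as the class and each training day's aggregated
activity vector as one sample. A test record is routed to the block
matching its demographics, its per-day class scores are averaged, and
the highest-scoring identifier is returned (ties to the lowest id).

Matchers:

* ``svm`` — linear support vector classification, selecting among five
  penalty/loss/formulation variants (L2-reg L2-loss dual and primal,
  L2-reg L1-loss, Crammer-Singer multiclass, L1-reg L2-loss) and a cost
  grid by leave-one-training-day-out cross-validation;
* ``rf`` — random forest, tuning the number of candidate features per
  split the same way;
* ``demographics_only`` — no activity features: the block membership
  alone, with the deterministic lowest-id tie-break;
* activity-only runs are ``svm``/``rf`` with ``blocking="none"``.

Confidences are softmax-normalised decision values (SVM) or vote
fractions (RF), giving the common [0, 1] scale needed for abstention in
the partial-overlap scenario.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .cohort import DemographicProfile
from .preprocess import FeatureTable

NO_MATCH = "<no-match>"

MODES = ("svm", "rf", "demographics_only", "activity_only")
BLOCKINGS = ("full", "age_sex", "none")

#: the five linear SVC variants considered during model selection
SVM_VARIANTS: tuple[dict, ...] = (
    {"penalty": "l2", "loss": "squared_hinge", "dual": True},
    {"penalty": "l2", "loss": "squared_hinge", "dual": False},
    {"penalty": "l2", "loss": "hinge", "dual": True},
    {"penalty": "l2", "loss": "squared_hinge", "dual": True, "multi_class": "crammer_singer"},
    {"penalty": "l1", "loss": "squared_hinge", "dual": False},
)
SVM_COST_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)
RF_TREES = 50


def block_key(
    profile: DemographicProfile, blocking: str = "full", age_bin_years: int | None = None
) -> tuple:
    """The demographic combination used for blocking.

    Age enters in integer years by default; ``age_bin_years`` coarsens
    it to bins of that width. ``blocking='none'`` maps everything to a
    single key.
    """
    if blocking not in BLOCKINGS:
        raise ValueError(f"unknown blocking {blocking!r}")
    if blocking == "none":
        return ()
    age = profile.age_years if age_bin_years is None else profile.age_years // age_bin_years
    if blocking == "age_sex":
        return (age, profile.sex)
    if not profile.is_imputed:
        raise ValueError("blocking requires imputed profiles (no missing attributes)")
    return (
        age,
        profile.sex,
        profile.education,
        profile.income,
        profile.race_ethnicity,
        profile.birth_country,
    )


def build_blocks(
    record_ids: Iterable[str],
    profiles: dict[str, DemographicProfile],
    blocking: str = "full",
    age_bin_years: int | None = None,
) -> dict[tuple, list[str]]:
    """Partition record ids by blocking key; members sorted, keys sortable."""
    blocks: dict[tuple, list[str]] = {}
    for rid in sorted(record_ids):
        blocks.setdefault(block_key(profiles[rid], blocking, age_bin_years), []).append(rid)
    return blocks


@dataclass
class AttackPrediction:
    """One test record's predicted identifier (or NO_MATCH) with a
    normalised confidence in [0, 1]."""

    record_id: str
    confidence: float


@dataclass
class _BlockMatcher:
    """Trained matcher for one block.

    ``members`` is the sorted class list. ``estimator`` is None for
    singleton and demographics-only blocks, where prediction is the
    lowest (or only) member id.
    """

    members: list[str]
    estimator: object | None = None
    selected: dict = field(default_factory=dict)

    def day_scores(self, X: np.ndarray) -> np.ndarray:
        """Per-day class scores over ``members`` (rows sum to 1)."""
        n = len(self.members)
        if self.estimator is None:
            return np.full((X.shape[0], n), 1.0 / n)
        if hasattr(self.estimator, "predict_proba"):
            proba = self.estimator.predict_proba(X)
        else:
            d = self.estimator.decision_function(X)
            if d.ndim == 1:  # binary: one margin column
                d = np.column_stack([-d, d])
            d = d - d.max(axis=1, keepdims=True)
            e = np.exp(d)
            proba = e / e.sum(axis=1, keepdims=True)
        classes = list(self.estimator.classes_)
        if classes != self.members:  # defensive; sklearn sorts classes
            order = [classes.index(m) for m in self.members]
            proba = proba[:, order]
        return proba


@dataclass
class BlockedModel:
    """The trained attack: a matcher per demographic block."""

    mode: str
    blocking: str
    interval_minutes: int
    train_days: tuple[int, ...]
    seed: int
    blocks: dict[tuple, _BlockMatcher]
    training_ids: list[str]
    age_bin_years: int | None = None
    tau: float = 0.0  # abstention threshold; 0 disables


def _day_folds(day_idx: np.ndarray):
    """Leave-one-training-day-out folds (train_pos, test_pos)."""
    for day in np.unique(day_idx):
        test = day_idx == day
        yield np.flatnonzero(~test), np.flatnonzero(test)


def _cv_score(factory, X, y, day_idx) -> float:
    """Mean held-out-day accuracy; -inf if any fold is degenerate."""
    scores = []
    for tr, te in _day_folds(day_idx):
        if len(np.unique(y[tr])) < 2:
            return -np.inf
        est = factory()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", UserWarning)
            est.fit(X[tr], y[tr])
        scores.append(float(np.mean(est.predict(X[te]) == y[te])))
    return float(np.mean(scores)) if scores else -np.inf


def _svm_factory(variant: dict, cost: float, seed: int):
    def make():
        kwargs = dict(variant)
        kwargs["dual"] = kwargs.get("dual", True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            clf = LinearSVC(C=cost, max_iter=5000, random_state=seed, **kwargs)
        return make_pipeline(StandardScaler(), clf)

    return make


def _rf_factory(max_features, seed: int):
    def make():
        return RandomForestClassifier(
            n_estimators=RF_TREES, max_features=max_features, random_state=seed
        )

    return make


def _rf_mtry_grid(p: int) -> list[int]:
    cands = {
        max(1, int(round(np.sqrt(p)))),
        max(1, p // 3),
        max(1, p // 2),
        p,
    }
    return sorted(min(c, p) for c in cands)


def train_block_matcher(
    X: np.ndarray,
    y: np.ndarray,
    day_idx: np.ndarray,
    mode: str,
    seed: int = 0,
) -> _BlockMatcher:
    """Fit the multiclass matcher for one block.

    One sample per (record, training day). Hyperparameters are selected
    by leave-one-training-day-out cross-validation; with fewer than two
    training days (or a singleton block) defaults are used without
    selection. Grid ties resolve to the earliest grid entry.
    """
    members = sorted(np.unique(y).tolist())
    if len(members) == 0:
        raise ValueError("block has no training rows")
    if len(members) == 1 or mode == "demographics_only":
        return _BlockMatcher(members=members)

    tunable = len(np.unique(day_idx)) >= 2
    if mode == "svm":
        best = (-np.inf, 0, None)
        grid = [(v, c) for v in SVM_VARIANTS for c in SVM_COST_GRID]
        if tunable:
            for gi, (variant, cost) in enumerate(grid):
                score = _cv_score(_svm_factory(variant, cost, seed), X, y, day_idx)
                if score > best[0]:
                    best = (score, gi, (variant, cost))
        variant, cost = best[2] if best[2] is not None else (SVM_VARIANTS[0], 1.0)
        est = _svm_factory(variant, cost, seed)()
        selected = {"variant": dict(variant), "cost": cost}
    elif mode == "rf":
        grid = _rf_mtry_grid(X.shape[1])
        best = (-np.inf, None)
        if tunable:
            for mtry in grid:
                score = _cv_score(_rf_factory(mtry, seed), X, y, day_idx)
                if score > best[0]:
                    best = (score, mtry)
        mtry = best[1] if best[1] is not None else max(1, int(round(np.sqrt(X.shape[1]))))
        est = _rf_factory(mtry, seed)()
        selected = {"max_features": mtry}
    else:
        raise ValueError(f"unknown mode {mode!r}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        est.fit(X, y)
    return _BlockMatcher(members=members, estimator=est, selected=selected)


def fit_blocked_model(
    train: FeatureTable,
    profiles: dict[str, DemographicProfile],
    mode: str = "rf",
    blocking: str = "full",
    seed: int = 0,
    age_bin_years: int | None = None,
) -> BlockedModel:
    """Train the full blocked attack model on a training feature table."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "activity_only":
        raise ValueError("express activity-only runs as mode='svm'/'rf' with blocking='none'")
    train_ids = train.record_ids
    blocks = build_blocks(train_ids, profiles, blocking, age_bin_years)
    feature_cols = train.feature_columns
    matchers: dict[tuple, _BlockMatcher] = {}
    for bi, key in enumerate(sorted(blocks)):
        member_ids = blocks[key]
        if mode == "demographics_only" or len(member_ids) == 1:
            matchers[key] = _BlockMatcher(members=member_ids)
            continue
        sub = train.table[train.table["record_id"].isin(member_ids)]
        X = sub[feature_cols].to_numpy(dtype=float)
        y = sub["record_id"].to_numpy()
        day_idx = sub["day_index"].to_numpy()
        matchers[key] = train_block_matcher(
            X, y, day_idx, mode, seed=(seed * 100003 + bi) % (2**31 - 1)
        )
    return BlockedModel(
        mode=mode,
        blocking=blocking,
        interval_minutes=train.interval_minutes,
        train_days=train.day_set,
        seed=seed,
        blocks=matchers,
        training_ids=train_ids,
        age_bin_years=age_bin_years,
    )


def predict_record(
    model: BlockedModel,
    test_rows: np.ndarray,
    profile: DemographicProfile,
) -> AttackPrediction:
    """Predict one test record from its test-day feature rows.

    Per-day class scores are averaged across test days; the argmax class
    is returned with its averaged score as confidence (ties to the
    lowest id). An unseen blocking key yields NO_MATCH with confidence
    1. Abstention (confidence below ``model.tau``) is applied by
    :func:`run_attack`, not here.
    """
    test_rows = np.atleast_2d(np.asarray(test_rows, dtype=float))
    m = 1440 // model.interval_minutes
    if test_rows.shape[1] != m:
        raise ValueError(
            f"feature length {test_rows.shape[1]} does not match model interval "
            f"k={model.interval_minutes} (expected {m})"
        )
    key = block_key(profile, model.blocking, model.age_bin_years)
    matcher = model.blocks.get(key)
    if matcher is None:
        return AttackPrediction(NO_MATCH, 1.0)
    if matcher.estimator is None:
        # singleton or demographics-only block: lowest member id
        return AttackPrediction(matcher.members[0], 1.0 / len(matcher.members))
    scores = matcher.day_scores(test_rows).mean(axis=0)
    best = int(np.argmax(scores))  # members sorted => first max is lowest id
    return AttackPrediction(matcher.members[best], float(scores[best]))


def apply_abstention(pred: AttackPrediction, tau: float) -> AttackPrediction:
    """NO_MATCH when confidence falls below the threshold."""
    if pred.record_id != NO_MATCH and pred.confidence < tau:
        return AttackPrediction(NO_MATCH, pred.confidence)
    return pred


ABSTENTION_GRID = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 2))


def calibrate_abstention(
    predictions: dict[str, AttackPrediction],
    known_ids: set[str],
    grid: Iterable[float] = ABSTENTION_GRID,
) -> float:
    """Choose the abstention threshold maximising partial-overlap
    accuracy on calibration predictions.

    ``predictions`` are raw (un-abstained) predictions keyed by true
    record id; records outside ``known_ids`` play the absent role and
    are correct only under NO_MATCH. Returns the lowest grid threshold
    attaining the maximum.
    """
    preds = sorted(predictions.items())
    if not preds:
        raise ValueError("no calibration predictions")
    best_tau, best_acc = None, -1.0
    for tau in grid:
        correct = 0
        for rid, p in preds:
            q = apply_abstention(p, tau)
            if rid in known_ids:
                correct += q.record_id == rid
            else:
                correct += q.record_id == NO_MATCH
        acc = correct / len(preds)
        if acc > best_acc + 1e-12:
            best_tau, best_acc = float(tau), acc
    return best_tau


def run_attack(
    train: FeatureTable,
    test: FeatureTable,
    profiles: dict[str, DemographicProfile],
    mode: str = "rf",
    blocking: str = "full",
    seed: int = 0,
    tau: float = 0.0,
    age_bin_years: int | None = None,
    model: Optional[BlockedModel] = None,
) -> dict[str, AttackPrediction]:
    """Train (unless ``model`` given) and predict every test record.

    Returns predictions keyed by the true test record id; deterministic
    given the seed. ``mode='activity_only'`` is shorthand for an
    unblocked random forest.
    """
    if mode == "activity_only":
        mode, blocking = "rf", "none"
    if set(train.day_set) & set(test.day_set):
        raise ValueError("training and testing day sets overlap")
    if model is None:
        model = fit_blocked_model(train, profiles, mode, blocking, seed, age_bin_years)
    model.tau = tau
    out: dict[str, AttackPrediction] = {}
    for rid in test.record_ids:
        pred = predict_record(model, test.rows_for(rid), profiles[rid])
        out[rid] = apply_abstention(pred, tau)
    return out
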