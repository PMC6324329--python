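"""Experiment orchestration: the aggregation sweep, day-split sweep,
partial-overlap scenario with abstention, and the full seeded grid.

Every sweep is a pure function of (plan, generator config, seeds): the
same inputs produce byte-identical report bundles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .attack import ABSTENTION_GRID, calibrate_abstention, run_attack
from .cohort import Cohort, DAY_LABELS
from .evaluate import EvaluationResult, adjust_results, build_report, evaluate_attack
from .preprocess import (
    DEFAULT_TEST_DAYS,
    DEFAULT_TRAIN_DAYS,
    STANDARD_INTERVALS,
    aggregate_intervals,
    build_split,
    prepare_cohort,
)
from .simulate import GeneratorConfig, generate_cohort

#: the six studied (train, test) weekday splits: the default Thu+Fri test
#: plus five alternatives, each 3 training and 2 disjoint testing days
DEFAULT_DAY_SPLITS: tuple[tuple[tuple[int, ...], tuple[int, ...]], ...] = (
    ((1, 2, 3), (4, 5)),  # test Thu+Fri (primary)
    ((2, 3, 5), (1, 4)),  # test Mon+Thu
    ((1, 3, 5), (2, 4)),  # test Tue+Thu
    ((1, 3, 4), (2, 5)),  # test Tue+Fri
    ((1, 2, 5), (3, 4)),  # test Wed+Thu
    ((1, 2, 4), (3, 5)),  # test Wed+Fri
)


def split_label(split: tuple[tuple[int, ...], tuple[int, ...]]) -> str:
    test = "+".join(DAY_LABELS[d - 1] for d in split[1])
    return f"test:{test}"


@dataclass
class ExperimentPlan:
    """The grid of experiment cells to run."""

    intervals: tuple[int, ...] = STANDARD_INTERVALS
    day_splits: tuple = (DEFAULT_DAY_SPLITS[0],)
    modes: tuple[str, ...] = ("svm", "rf", "demographics_only")
    blockings: tuple[str, ...] = ("full",)
    overlap_scenario: str = "full"  # full | partial
    overlap_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seeds: tuple[int, ...] = (0,)
    age_bin_years: int | None = None

    def __post_init__(self) -> None:
        for k in self.intervals:
            if 1440 % k:
                raise ValueError(f"interval {k} does not divide 1440")
        for train_days, test_days in self.day_splits:
            if set(train_days) & set(test_days):
                raise ValueError(f"overlapping day split {(train_days, test_days)}")
        if self.overlap_scenario not in ("full", "partial"):
            raise ValueError(f"unknown overlap scenario {self.overlap_scenario!r}")

    @property
    def n_cells(self) -> int:
        return (
            len(self.intervals)
            * len(self.day_splits)
            * len(self.modes)
            * len(self.blockings)
            * len(self.seeds)
        )


def sweep_aggregation(
    cohort: Cohort,
    intervals: Sequence[int] = STANDARD_INTERVALS,
    modes: Sequence[str] = ("rf",),
    blocking: str = "full",
    train_days: Sequence[int] = DEFAULT_TRAIN_DAYS,
    test_days: Sequence[int] = DEFAULT_TEST_DAYS,
    seed: int = 0,
    age_bin_years: int | None = None,
) -> list[EvaluationResult]:
    """Accuracy per (mode, interval width) on one prepared cohort.

    The day partition is fixed across widths so only the temporal
    coarseness varies. The cohort must already be prepared (complete
    weekday records, imputed profiles).
    """
    profiles = cohort.profiles()
    results = []
    for k in intervals:
        train, test = build_split(aggregate_intervals(cohort, k), k, train_days, test_days)
        for mode in modes:
            preds = run_attack(
                train, test, profiles, mode, blocking, seed=seed, age_bin_years=age_bin_years
            )
            results.append(
                evaluate_attack(
                    preds,
                    pool_size=len(train.record_ids),
                    labels={
                        "mode": mode,
                        "blocking": blocking,
                        "interval": k,
                        "split": split_label((tuple(train_days), tuple(test_days))),
                        "scenario": "full_overlap",
                        "population": cohort.population_label,
                        "seed": seed,
                    },
                )
            )
    return results


def sweep_day_splits(
    cohort: Cohort,
    day_splits: Sequence = DEFAULT_DAY_SPLITS,
    k: int = 20,
    mode: str = "rf",
    blocking: str = "full",
    seed: int = 0,
    age_bin_years: int | None = None,
) -> list[EvaluationResult]:
    """Accuracy per (train, test) weekday split at one width."""
    profiles = cohort.profiles()
    agg = aggregate_intervals(cohort, k)
    results = []
    for split in day_splits:
        train_days, test_days = split
        train, test = build_split(agg, k, train_days, test_days)
        preds = run_attack(
            train, test, profiles, mode, blocking, seed=seed, age_bin_years=age_bin_years
        )
        results.append(
            evaluate_attack(
                preds,
                pool_size=len(train.record_ids),
                labels={
                    "mode": mode,
                    "blocking": blocking,
                    "interval": k,
                    "split": split_label(split),
                    "scenario": "full_overlap",
                    "population": cohort.population_label,
                    "seed": seed,
                },
            )
        )
    return results


def partition_overlap(
    record_ids: Sequence[str],
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> tuple[list[str], list[str], list[str]]:
    """Seeded partition into (both, train-only, test-only) id lists."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"overlap fractions {fractions} do not sum to 1")
    ids = sorted(record_ids)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n = len(ids)
    n_both = int(round(fractions[0] * n))
    n_train_only = int(round(fractions[1] * n))
    both = sorted(ids[j] for j in perm[:n_both])
    train_only = sorted(ids[j] for j in perm[n_both : n_both + n_train_only])
    test_only = sorted(ids[j] for j in perm[n_both + n_train_only :])
    return both, train_only, test_only


def run_partial_overlap(
    cohort: Cohort,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    mode: str = "rf",
    blocking: str = "full",
    k: int = 20,
    tau: float | None = None,
    age_bin_years: int | None = None,
) -> EvaluationResult:
    """The partial-overlap scenario with confidence-based abstention.

    Record ids are partitioned (both, train-only, test-only) by a
    seeded draw; the model is trained on the training pool's Mon-Wed
    rows and evaluated on the testing pool's Thu-Fri rows, where a
    NO_MATCH on a test-only record counts as correct. With ``tau=None``
    the abstention threshold is calibrated on a pseudo-absent split of
    the training pool: a quarter of training records are withheld from a
    calibration model (trained on Mon-Tue), their reserved Wednesday
    rows play the absent role, and the grid threshold maximising
    calibration accuracy is chosen.
    """
    both, train_only, test_only = partition_overlap(cohort.record_ids, fractions, seed)
    train_ids = sorted(both + train_only)
    test_ids = sorted(both + test_only)
    profiles = cohort.profiles()
    agg = aggregate_intervals(cohort, k)

    if tau is None:
        rng = np.random.default_rng(seed + 1)
        perm = rng.permutation(len(train_ids))
        n_known = int(round(len(train_ids) * 0.75))
        pseudo_known = sorted(train_ids[j] for j in perm[:n_known])
        cal_train, cal_test = build_split(
            agg[agg["record_id"].isin(train_ids)], k, train_days=(1, 2), test_days=(3,)
        )
        cal_train_known = type(cal_train)(
            cal_train.interval_minutes,
            "training",
            cal_train.day_set,
            cal_train.table[cal_train.table["record_id"].isin(pseudo_known)].reset_index(
                drop=True
            ),
        )
        cal_preds = run_attack(
            cal_train_known,
            cal_test,
            profiles,
            mode,
            blocking,
            seed=seed,
            age_bin_years=age_bin_years,
        )
        tau = calibrate_abstention(cal_preds, set(pseudo_known), ABSTENTION_GRID)

    train, _ = build_split(agg[agg["record_id"].isin(train_ids)], k, DEFAULT_TRAIN_DAYS, DEFAULT_TEST_DAYS)
    _, test = build_split(agg[agg["record_id"].isin(test_ids)], k, DEFAULT_TRAIN_DAYS, DEFAULT_TEST_DAYS)
    preds = run_attack(
        train, test, profiles, mode, blocking, seed=seed, tau=tau, age_bin_years=age_bin_years
    )
    result = evaluate_attack(
        preds,
        pool_size=len(test_ids),
        scenario="partial_overlap",
        training_ids=train_ids,
        labels={
            "mode": mode,
            "blocking": blocking,
            "interval": k,
            "split": split_label(((1, 2, 3), (4, 5))),
            "scenario": "partial_overlap",
            "population": cohort.population_label,
            "seed": seed,
            "tau": tau,
            "n_both": len(both),
            "n_train_only": len(train_only),
            "n_test_only": len(test_only),
        },
    )
    return result


def run_full_experiment(
    plan: ExperimentPlan,
    configs: GeneratorConfig | Sequence[GeneratorConfig],
    out_dir: str | Path | None = None,
) -> dict:
    """Run every cell of the plan on freshly generated cohorts.

    One cohort per generator config (e.g. one adult, one child).
    Bonferroni m is the total number of cells executed. When ``out_dir``
    is given, writes ``results.csv``, ``report.json`` and per-cell
    prediction dumps under ``predictions/``; outputs are byte-identical
    across reruns with the same plan and configs.
    """
    if isinstance(configs, GeneratorConfig):
        configs = [configs]
    all_results: list[EvaluationResult] = []
    dumps: dict[str, dict] = {}
    for config in configs:
        raw = generate_cohort(config)
        cohort, log = prepare_cohort(raw)
        profiles = cohort.profiles()
        for seed in plan.seeds:
            if plan.overlap_scenario == "partial":
                for mode in plan.modes:
                    for blocking in plan.blockings:
                        for k in plan.intervals:
                            res = run_partial_overlap(
                                cohort,
                                plan.overlap_fractions,
                                seed=seed,
                                mode=mode,
                                blocking=blocking,
                                k=k,
                                age_bin_years=plan.age_bin_years,
                            )
                            res.labels["exclusions"] = dict(log)
                            all_results.append(res)
                continue
            for train_days, test_days in plan.day_splits:
                for k in plan.intervals:
                    train, test = build_split(
                        aggregate_intervals(cohort, k), k, train_days, test_days
                    )
                    for mode in plan.modes:
                        for blocking in plan.blockings:
                            preds = run_attack(
                                train,
                                test,
                                profiles,
                                mode,
                                blocking,
                                seed=seed,
                                age_bin_years=plan.age_bin_years,
                            )
                            res = evaluate_attack(
                                preds,
                                pool_size=len(train.record_ids),
                                labels={
                                    "mode": mode,
                                    "blocking": blocking,
                                    "interval": k,
                                    "split": split_label((train_days, test_days)),
                                    "scenario": "full_overlap",
                                    "population": cohort.population_label,
                                    "seed": seed,
                                },
                            )
                            all_results.append(res)
                            cell = (
                                f"{cohort.population_label}_{mode}_{blocking}_k{k}_"
                                f"{split_label((train_days, test_days)).replace(':', '-')}_s{seed}"
                            )
                            dumps[cell] = {
                                rid: [p.record_id, round(p.confidence, 6)]
                                for rid, p in sorted(preds.items())
                            }

    adjust_results(all_results)
    report = build_report(all_results)
    bundle = {
        "version": __version__,
        "bonferroni_m": len(all_results),
        "n_cells": len(all_results),
        "results": [r.to_row() for r in all_results],
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report["tidy"].to_csv(out_dir / "results.csv", index=False)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(bundle, fh, indent=2, sort_keys=True)
            fh.write("\n")
        pred_dir = out_dir / "predictions"
        pred_dir.mkdir(exist_ok=True)
        for cell, preds in sorted(dumps.items()):
            with open(pred_dir / f"{cell}.json", "w") as fh:
                json.dump(preds, fh, indent=0, sort_keys=True)
                fh.write("\n")
    return bundle
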