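"""Matching accuracy, the exact binomial test against the chance null,
Bonferroni adjustment, and report tables.

Under the null hypothesis that every match is pure chance, the number
of correct matches is Binomial(n_test, 1/N) with N the candidate pool
size (training individuals in the full-overlap scenario, testing
individuals under partial overlap). The reported p-value is the exact
upper tail P(X >= n_matched).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .attack import NO_MATCH, AttackPrediction

ALPHA = 0.05


@dataclass
class EvaluationResult:
    """Match counts and significance for one experiment cell."""

    n_test: int
    n_matched: int
    p0: float
    p_raw: float
    p_adj: float | None = None
    labels: dict = field(default_factory=dict)

    @property
    def accuracy(self) -> float:
        return self.n_matched / self.n_test if self.n_test else float("nan")

    def to_row(self) -> dict:
        row = dict(self.labels)
        row.update(
            n_test=self.n_test,
            n_matched=self.n_matched,
            accuracy=self.accuracy,
            p0=self.p0,
            p_raw=self.p_raw,
            p_adj=self.p_adj,
        )
        return row


def match_accuracy(
    predictions: Mapping[str, AttackPrediction],
    truth_ids: Iterable[str],
    scenario: str = "full_overlap",
    training_ids: Iterable[str] | None = None,
) -> tuple[int, int]:
    """Count correct matches.

    A named prediction is correct iff it equals the true id. Under
    ``partial_overlap``, NO_MATCH is correct iff the true id is absent
    from ``training_ids`` (a correct identification of "no match" counts
    as a correct match).
    """
    truth = set(truth_ids)
    unknown = set(predictions) - truth
    if unknown:
        raise ValueError(f"predictions for unknown test records: {sorted(unknown)[:5]}")
    if scenario not in ("full_overlap", "partial_overlap"):
        raise ValueError(f"unknown scenario {scenario!r}")
    if scenario == "partial_overlap":
        if training_ids is None:
            raise ValueError("partial_overlap scenario requires training_ids")
        training = set(training_ids)
    n_matched = 0
    for rid in truth:
        pred = predictions.get(rid)
        if pred is None:
            continue  # missing prediction is simply not a match
        if pred.record_id == NO_MATCH:
            if scenario == "partial_overlap" and rid not in training:
                n_matched += 1
        elif pred.record_id == rid:
            n_matched += 1
    return n_matched, len(truth)


def binomial_match_test(n_matched: int, n_test: int, p0: float) -> float:
    """Exact upper-tail binomial probability P(X >= n_matched)."""
    if not 0 <= n_matched <= n_test:
        raise ValueError(f"invalid counts: {n_matched} matches of {n_test}")
    if not 0.0 < p0 <= 1.0:
        raise ValueError(f"chance probability {p0} outside (0, 1]")
    if n_matched == 0:
        return 1.0
    return float(stats.binom.sf(n_matched - 1, n_test, p0))


def bonferroni_adjust(p_values: Iterable[float], m: int) -> list[float]:
    """min(1, m * p) for each value; m must cover all values."""
    ps = list(p_values)
    if m < len(ps):
        raise ValueError(f"m={m} smaller than the number of tests ({len(ps)})")
    return [min(1.0, m * p) for p in ps]


def evaluate_attack(
    predictions: Mapping[str, AttackPrediction],
    pool_size: int,
    scenario: str = "full_overlap",
    training_ids: Iterable[str] | None = None,
    labels: dict | None = None,
) -> EvaluationResult:
    """Accuracy plus the raw binomial p-value for one experiment cell."""
    n_matched, n_test = match_accuracy(
        predictions, list(predictions), scenario, training_ids
    )
    p0 = 1.0 / pool_size
    return EvaluationResult(
        n_test=n_test,
        n_matched=n_matched,
        p0=p0,
        p_raw=binomial_match_test(n_matched, n_test, p0),
        labels=dict(labels or {}),
    )


def adjust_results(results: list[EvaluationResult], m: int | None = None) -> list[EvaluationResult]:
    """Fill in Bonferroni-adjusted p-values (m defaults to the number of
    cells in the list, reported alongside)."""
    m = len(results) if m is None else m
    adjusted = bonferroni_adjust([r.p_raw for r in results], m)
    for r, pa in zip(results, adjusted):
        r.p_adj = pa
        r.labels.setdefault("bonferroni_m", m)
    return results


def _stars(p_adj: float | None) -> str:
    return "*" if p_adj is not None and p_adj < ALPHA else ""


def build_report(results: list[EvaluationResult]) -> dict[str, pd.DataFrame]:
    """Tidy results plus the two standard grids.

    ``by_mode``: rows (population, dataset/scenario), columns modes, at
    one aggregation width. ``by_interval``: rows modes, columns interval
    widths. Cells show percent accuracy; an appended '*' marks
    Bonferroni-adjusted significance at alpha=.05.
    """
    if not results:
        raise ValueError("no results to report")
    tidy = pd.DataFrame([r.to_row() for r in results])
    report = {"tidy": tidy}

    def cell(acc, p_adj):
        return f"{100 * acc:.1f}{_stars(p_adj)}"

    if {"mode", "population"} <= set(tidy.columns):
        sub = tidy.copy()
        sub["cell"] = [cell(a, p) for a, p in zip(sub["accuracy"], sub["p_adj"])]
        report["by_mode"] = sub.pivot_table(
            index="population", columns="mode", values="cell", aggfunc="first"
        )
    if {"mode", "interval"} <= set(tidy.columns):
        sub = tidy[tidy["interval"].notna()].copy()
        if len(sub):
            sub["cell"] = [cell(a, p) for a, p in zip(sub["accuracy"], sub["p_adj"])]
            report["by_interval"] = sub.pivot_table(
                index="mode", columns="interval", values="cell", aggfunc="first"
            )
    return report
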