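"""Comparison of a sorting against ground truth with a timing tolerance.

A sorted event s matches a ground-truth event t when |t - s| <= Delta, with
Delta an acceptable firing-time error (default 1 ms) assumed shorter than half
the refractory period of any true neuron.  For a (ground-truth unit l, sorted
unit k) pair the number of matches is

    n_match(l, k) = #{ i : |t_i - s_j| <= Delta for some j },

so each ground-truth event contributes at most once even when several sorted
events fall inside its tolerance window.  Misses and false positives follow by
subtraction from the train sizes N_l and M_k, and the per-pair accuracy is

    a(l, k) = n_match / (n_match + n_miss + n_fp),

a balance of precision p = n_match / (n_match + n_fp) and recall
r = n_match / (n_match + n_miss): for n_match > 0, 1/a = 1/p + 1/r - 1.
Each ground-truth unit is scored against its best-matching sorted unit
(argmax of a over k, ties to the smallest label).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .mda import Firings

__all__ = [
    "ComparisonParams",
    "MatchCounts",
    "UnitComparison",
    "count_matches",
    "match_counts_all",
    "pair_accuracy",
    "best_match",
    "compare_sorting",
    "categorize_events",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ComparisonParams:
    """Timing tolerance Delta in milliseconds plus the rate to convert it."""

    sample_rate: float
    delta_ms: float = 1.0

    def __post_init__(self):
        if self.delta_ms <= 0:
            raise ValueError("delta_ms must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def delta_samples(self) -> int:
        return max(1, round(self.delta_ms * self.sample_rate / 1000.0))


@dataclass(frozen=True)
class MatchCounts:
    """Match/miss/false-positive counts for one (ground-truth, sorted) pair."""

    gt_label: int
    sorted_label: int
    n_match: int
    n_miss: int
    n_fp: int
    num_gt_events: int
    num_sorted_events: int

    def __post_init__(self):
        assert self.n_match <= min(self.num_gt_events, self.num_sorted_events)
        assert self.n_miss == self.num_gt_events - self.n_match >= 0
        assert self.n_fp == self.num_sorted_events - self.n_match >= 0


@dataclass(frozen=True)
class UnitComparison:
    """Per-ground-truth-unit scores against its best-matching sorted unit."""

    gt_label: int
    best_sorted_label: Optional[int]
    accuracy: float
    precision: float
    recall: float
    n_match: int
    n_miss: int
    n_fp: int
    num_gt_events: int
    num_sorted_events: int


def _check_sorted(times: np.ndarray, name: str) -> np.ndarray:
    times = np.asarray(times, dtype=np.float64)
    if times.ndim != 1:
        raise ValueError(f"{name} must be 1-D")
    if len(times) > 1 and np.any(np.diff(times) < 0):
        raise ValueError(f"{name} must be nondecreasing")
    return times


def count_matches(gt_times, sorted_times, delta_samples: int) -> int:
    """Number of ground-truth events with at least one sorted event within Delta.

    Both inputs must be nondecreasing.  Each ground-truth event is counted at
    most once regardless of how many sorted events fall in its window.
    """
    gt = _check_sorted(gt_times, "gt_times")
    srt = _check_sorted(sorted_times, "sorted_times")
    if delta_samples < 1:
        raise ValueError("delta_samples must be >= 1")
    if len(gt) == 0 or len(srt) == 0:
        return 0
    # nearest sorted neighbor of each gt event via binary search
    idx = np.searchsorted(srt, gt)
    left = np.clip(idx - 1, 0, len(srt) - 1)
    right = np.clip(idx, 0, len(srt) - 1)
    dist = np.minimum(np.abs(gt - srt[left]), np.abs(gt - srt[right]))
    return int(np.count_nonzero(dist <= delta_samples))


def match_counts_all(
    gt: Firings, sorting: Firings, params: ComparisonParams
) -> dict[tuple[int, int], MatchCounts]:
    """MatchCounts for every (ground-truth unit, sorted unit) pair."""
    gt_units = gt.unit_labels
    if len(gt_units) == 0:
        raise ValueError("ground truth contains no events; nothing to evaluate")
    sorted_units = sorting.unit_labels
    delta = params.delta_samples
    gt_trains = {l: gt.times_for(l) for l in gt_units}
    sorted_trains = {k: sorting.times_for(k) for k in sorted_units}
    out: dict[tuple[int, int], MatchCounts] = {}
    for l, t in gt_trains.items():
        for k, s in sorted_trains.items():
            m = count_matches(t, s, delta)
            out[(int(l), int(k))] = MatchCounts(
                gt_label=int(l),
                sorted_label=int(k),
                n_match=m,
                n_miss=len(t) - m,
                n_fp=len(s) - m,
                num_gt_events=len(t),
                num_sorted_events=len(s),
            )
    return out


def pair_accuracy(counts: MatchCounts) -> float:
    """a = n_match / (n_match + n_miss + n_fp); NaN when all counts are zero."""
    denom = counts.n_match + counts.n_miss + counts.n_fp
    if denom == 0:
        return float("nan")
    return counts.n_match / denom


def best_match(accuracies: dict[int, float]) -> Optional[int]:
    """Sorted label with highest accuracy; ties to smallest label; None if max is 0."""
    if not accuracies:
        return None
    best_label, best_acc = None, 0.0
    for k in sorted(accuracies):
        a = accuracies[k]
        if np.isnan(a):
            continue
        if a > best_acc:
            best_label, best_acc = k, a
    return best_label


def _warn_refractory(gt: Firings, delta_samples: int) -> None:
    for l in gt.unit_labels:
        t = gt.times_for(l)
        if len(t) > 1 and np.min(np.diff(t)) < 2 * delta_samples:
            logger.warning(
                "ground-truth unit %d has inter-event gaps < 2*Delta "
                "(matching assumes Delta below half the refractory period)",
                l,
            )


def compare_sorting(
    gt: Firings, sorting: Firings, params: ComparisonParams
) -> list[UnitComparison]:
    """Score every ground-truth unit against its best-matching sorted unit.

    Multiple ground-truth units may share a best match; when that happens it
    is reported via logging but not prevented.
    """
    _warn_refractory(gt, params.delta_samples)
    counts = match_counts_all(gt, sorting, params)
    results: list[UnitComparison] = []
    best_of: dict[int, list[int]] = {}
    for l in gt.unit_labels:
        l = int(l)
        acc = {k: pair_accuracy(c) for (gl, k), c in counts.items() if gl == l}
        k_hat = best_match(acc)
        if k_hat is None:
            n_gt = next(c.num_gt_events for (gl, _), c in counts.items() if gl == l) \
                if acc else len(gt.times_for(l))
            results.append(
                UnitComparison(l, None, 0.0, 0.0, 0.0, 0, n_gt, 0, n_gt, 0)
            )
            continue
        c = counts[(l, k_hat)]
        p = c.n_match / (c.n_match + c.n_fp) if c.n_match + c.n_fp else 0.0
        r = c.n_match / (c.n_match + c.n_miss) if c.n_match + c.n_miss else 0.0
        results.append(
            UnitComparison(
                gt_label=l,
                best_sorted_label=k_hat,
                accuracy=acc[k_hat],
                precision=p,
                recall=r,
                n_match=c.n_match,
                n_miss=c.n_miss,
                n_fp=c.n_fp,
                num_gt_events=c.num_gt_events,
                num_sorted_events=c.num_sorted_events,
            )
        )
        best_of.setdefault(k_hat, []).append(l)
    shared = {k: ls for k, ls in best_of.items() if len(ls) > 1}
    if shared:
        logger.warning("sorted unit(s) shared as best match: %s", shared)
    return results


def categorize_events(
    gt_times, sorted_times, delta_samples: int
) -> tuple[np.ndarray, np.ndarray]:
    """Label each event: ground-truth as 'matched'/'missed', sorted as
    'matched'/'false_positive'.

    Matched sorted events are assigned greedily (each matched ground-truth
    event claims its nearest unclaimed sorted event), so under the refractory
    assumption the matched counts agree with :func:`count_matches` on both
    sides.
    """
    gt = _check_sorted(gt_times, "gt_times")
    srt = _check_sorted(sorted_times, "sorted_times")
    gt_cat = np.full(len(gt), "missed", dtype=object)
    srt_cat = np.full(len(srt), "false_positive", dtype=object)
    used = np.zeros(len(srt), dtype=bool)
    for i, t in enumerate(gt):
        lo = np.searchsorted(srt, t - delta_samples, side="left")
        hi = np.searchsorted(srt, t + delta_samples, side="right")
        window = np.arange(lo, hi)
        if len(window) == 0:
            continue
        gt_cat[i] = "matched"
        free = window[~used[window]]
        if len(free):
            j = free[np.argmin(np.abs(srt[free] - t))]
            used[j] = True
            srt_cat[j] = "matched"
    return gt_cat, srt_cat
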