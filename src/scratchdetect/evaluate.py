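"""Evaluation against manually labeled ground truth.

A predicted island and a labeled scratch bout *match* when they overlap by
strictly more than 50 ms (two scratch periods — at least two swipes were
caught). Partial overlaps, islands spanning several bouts and bouts spanning
several islands are all handled by one rule: build the bipartite overlap
graph and count one true positive per connected component that contains at
least one island and one bout. Islands connected to no bout are false
positives.

    sensitivity = TP / #bouts          FDR = FP / (TP + FP)

Sweeping the classifier cutoff over the distinct predicted probabilities
traces the sensitivity/FDR tradeoff curve. Subsampling utilities reproduce
the class-balance and training-size experiments, and :func:`scratch_rate`
turns event times into a kernel-smoothed bouts-per-minute curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .audio_io import LabeledInterval, LabelTrack
from .classify import Prediction, classify_at_cutoff
from .islands import CandidateIsland

__all__ = [
    "MatchCounts",
    "TradeoffPoint",
    "RateSeries",
    "match_intervals",
    "sensitivity",
    "fdr",
    "label_islands",
    "tradeoff_curve",
    "sensitivity_at_fdr",
    "stratified_subsample",
    "uniform_subsample",
    "scratch_rate",
]

MIN_OVERLAP_S = 0.050

Interval = tuple[float, float]


@dataclass(frozen=True)
class MatchCounts:
    """True/false-positive bookkeeping for one evaluation."""

    n_true_positive: int
    n_false_positive: int
    n_bouts: int
    n_predicted: int

    def __post_init__(self) -> None:
        if self.n_true_positive > min(self.n_bouts, self.n_predicted):
            raise ValueError("more true positives than bouts or predictions")


@dataclass(frozen=True)
class TradeoffPoint:
    cutoff: float
    sensitivity: float
    fdr: float


@dataclass
class RateSeries:
    """Kernel-smoothed event rate in bouts per minute."""

    times_s: np.ndarray
    rate_per_min: np.ndarray


def _as_intervals(predicted) -> list[Interval]:
    out = []
    for p in predicted:
        if isinstance(p, CandidateIsland):
            out.append((p.start_s, p.end_s))
        elif isinstance(p, LabeledInterval):
            out.append((p.onset_s, p.offset_s))
        else:
            a, b = p
            out.append((float(a), float(b)))
    return sorted(out)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        self.parent[self.find(i)] = self.find(j)


def match_intervals(
    predicted,
    truth,
    min_overlap_s: float = MIN_OVERLAP_S,
) -> MatchCounts:
    """Count true and false positives under the >50 ms overlap rule.

    ``predicted`` is a list of islands or (start, end) pairs; ``truth`` is a
    LabelTrack (its scratch intervals are used) or a list of non-overlapping
    intervals. One TP per connected component of the overlap graph containing
    both kinds of interval.
    """
    if isinstance(truth, LabelTrack):
        truth_iv = [(iv.onset_s, iv.offset_s) for iv in truth.scratch_intervals()]
    else:
        truth_iv = _as_intervals(truth)
    truth_iv = sorted(truth_iv)
    for (a1, b1), (a2, b2) in zip(truth_iv, truth_iv[1:]):
        if min(b1, b2) - max(a1, a2) > 0:
            raise ValueError("truth scratch intervals must not overlap")
    pred_iv = _as_intervals(predicted)
    n_p, n_t = len(pred_iv), len(truth_iv)
    uf = _UnionFind(n_p + n_t)
    has_edge_p = np.zeros(n_p, dtype=bool)
    # two-pointer sweep over sorted intervals
    j0 = 0
    for i, (ps, pe) in enumerate(pred_iv):
        while j0 < n_t and truth_iv[j0][1] <= ps:
            j0 += 1
        j = j0
        while j < n_t and truth_iv[j][0] < pe:
            ts, te = truth_iv[j]
            if min(pe, te) - max(ps, ts) > min_overlap_s:
                uf.union(i, n_p + j)
                has_edge_p[i] = True
            j += 1
    comp_has_pred: dict[int, bool] = {}
    comp_has_truth: dict[int, bool] = {}
    for i in range(n_p):
        r = uf.find(i)
        comp_has_pred[r] = True
    for j in range(n_t):
        r = uf.find(n_p + j)
        comp_has_truth[r] = True
    tp = sum(1 for r in comp_has_truth if comp_has_pred.get(r, False))
    fp = int(np.sum(~has_edge_p))
    return MatchCounts(
        n_true_positive=tp, n_false_positive=fp,
        n_bouts=n_t, n_predicted=n_p,
    )


def sensitivity(counts: MatchCounts) -> float:
    """TP / #bouts."""
    if counts.n_bouts == 0:
        raise ValueError("sensitivity undefined with zero labeled bouts")
    return counts.n_true_positive / counts.n_bouts


def fdr(counts: MatchCounts) -> float:
    """FP / (TP + FP); 0 by convention when nothing was predicted."""
    denom = counts.n_true_positive + counts.n_false_positive
    if denom == 0:
        return 0.0
    return counts.n_false_positive / denom


def label_islands(
    islands: list[CandidateIsland],
    truth: LabelTrack,
    min_overlap_s: float = MIN_OVERLAP_S,
) -> np.ndarray:
    """Training labels: an island is positive iff it overlaps some labeled
    scratch bout by more than ``min_overlap_s`` (the same rule used for
    scoring)."""
    bouts = truth.scratch_intervals()
    labels = np.zeros(len(islands), dtype=int)
    for i, isl in enumerate(islands):
        for b in bouts:
            if min(isl.end_s, b.offset_s) - max(isl.start_s, b.onset_s) > min_overlap_s:
                labels[i] = 1
                break
    return labels


def tradeoff_curve(
    predictions: list[Prediction],
    islands: list[CandidateIsland],
    truth: LabelTrack,
    use_adjusted: bool = False,
    min_overlap_s: float = MIN_OVERLAP_S,
) -> list[TradeoffPoint]:
    """Sensitivity/FDR at every distinct predicted probability as cutoff."""
    by_id = {isl.island_id: isl for isl in islands}
    probs = np.asarray([p.probability(use_adjusted) for p in predictions])
    cutoffs = np.unique(probs[np.isfinite(probs)])
    points: list[TradeoffPoint] = []
    for cutoff in cutoffs:
        keep = classify_at_cutoff(predictions, float(cutoff), use_adjusted)
        pred_iv = [by_id[p.island_id] for p, k in zip(predictions, keep) if k]
        counts = match_intervals(pred_iv, truth, min_overlap_s)
        points.append(TradeoffPoint(
            cutoff=float(cutoff),
            sensitivity=sensitivity(counts),
            fdr=fdr(counts),
        ))
    return points


def sensitivity_at_fdr(points: list[TradeoffPoint], max_fdr: float) -> float:
    """Highest sensitivity among operating points with FDR <= ``max_fdr``
    (0 if none qualifies)."""
    ok = [p.sensitivity for p in points if p.fdr <= max_fdr]
    return max(ok) if ok else 0.0


def stratified_subsample(
    labels: np.ndarray,
    target_positive_fraction: float,
    seed: int = 0,
) -> np.ndarray:
    """Indices realizing a target class balance.

    Keeps the class that must not shrink in full and subsamples the other
    without replacement, mimicking a recording with a different scratch rate.
    """
    labels = np.asarray(labels, dtype=int)
    if not 0 < target_positive_fraction < 1:
        raise ValueError("target fraction must be in (0, 1)")
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes required")
    rng = np.random.default_rng(seed)
    current = len(pos) / len(labels)
    f = target_positive_fraction
    if f <= current:
        n_pos = int(np.ceil(f * len(neg) / (1.0 - f)))
        if n_pos < 1 or n_pos > len(pos):
            raise ValueError("target fraction unachievable")
        keep_pos = rng.choice(pos, size=n_pos, replace=False)
        keep_neg = neg
    else:
        n_neg = int(np.ceil(len(pos) * (1.0 - f) / f))
        if n_neg < 1 or n_neg > len(neg):
            raise ValueError("target fraction unachievable")
        keep_neg = rng.choice(neg, size=n_neg, replace=False)
        keep_pos = pos
    achieved = len(keep_pos) / (len(keep_pos) + len(keep_neg))
    if abs(achieved - f) > 0.02:
        raise ValueError(
            f"target fraction {f:.3f} unachievable (closest: {achieved:.3f})")
    return np.sort(np.concatenate([keep_pos, keep_neg]))


def uniform_subsample(n_total: int, n: int, seed: int = 0) -> np.ndarray:
    """Simple random sample of ``n`` indices without replacement."""
    if n > n_total:
        raise ValueError(f"cannot sample {n} from {n_total}")
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(n_total, size=n, replace=False))


def scratch_rate(
    event_times_s: np.ndarray,
    bandwidth_s: float = 60.0,
    grid_s: np.ndarray | None = None,
    duration_s: float | None = None,
    grid_step_s: float = 1.0,
) -> RateSeries:
    """Gaussian-kernel estimate of the scratch-bout rate over time.

    Events are reflected at the recording boundaries so the integral of the
    rate over the recording equals the event count; output is in bouts per
    minute.
    """
    if bandwidth_s <= 0:
        raise ValueError("bandwidth must be positive")
    events = np.asarray(event_times_s, dtype=np.float64)
    if grid_s is None:
        if duration_s is None:
            duration_s = float(events.max()) if len(events) else 0.0
        grid_s = np.arange(0.0, duration_s + grid_step_s / 2, grid_step_s)
    grid_s = np.asarray(grid_s, dtype=np.float64)
    if len(events) == 0:
        return RateSeries(times_s=grid_s, rate_per_min=np.zeros_like(grid_s))
    lo, hi = 0.0, float(duration_s if duration_s is not None else grid_s[-1])
    # boundary reflection keeps unit mass per event inside [lo, hi]
    all_events = np.concatenate([events, 2 * lo - events, 2 * hi - events])
    diffs = grid_s[:, None] - all_events[None, :]
    dens = np.exp(-0.5 * (diffs / bandwidth_s) ** 2).sum(axis=1)
    dens /= bandwidth_s * np.sqrt(2 * np.pi)
    return RateSeries(times_s=grid_s, rate_per_min=dens * 60.0)
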