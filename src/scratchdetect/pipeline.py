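"""End-to-end workflows built from the library modules.

These functions wire the standard experiment designs together: calibrate the
first pass, collect and label islands, learn the template, featurize, train,
predict (out-of-bag or held-out), and trace tradeoff curves. They are what
the command-line interface, the test suite and the reproduction script call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .audio_io import AudioRecording, LabelTrack
from .classify import (
    ForestModel,
    Prediction,
    neighborhood_adjust,
    predict,
    predict_oob,
    train_forest,
)
from .config import RunConfig
from .evaluate import (
    TradeoffPoint,
    label_islands,
    sensitivity_at_fdr,
    tradeoff_curve,
)
from .features import (
    FeatureVector,
    TemplateSpectrum,
    feature_frame,
    featurize_islands,
    learn_template,
)
from .islands import (
    CandidateIsland,
    calibrate_threshold,
    capture_fraction,
    find_candidate_islands,
)

__all__ = [
    "PreparedCorpus",
    "prepare_corpus",
    "split_half",
    "holdout_tradeoff",
    "oob_tradeoff",
    "operating_point",
]


@dataclass
class PreparedCorpus:
    """A recording taken through the first pass and feature extraction."""

    recording: AudioRecording
    truth: LabelTrack
    threshold_h: float
    islands: list[CandidateIsland]
    labels: np.ndarray
    template: TemplateSpectrum
    features: list[FeatureVector]
    config: RunConfig = field(repr=False, default=None)

    @property
    def capture(self) -> float:
        return capture_fraction(self.islands, self.truth)


def prepare_corpus(
    recording: AudioRecording,
    truth: LabelTrack,
    config: RunConfig,
    template_from: LabelTrack | None = None,
) -> PreparedCorpus:
    """Calibrate h, collect and label islands, learn the template, featurize.

    ``template_from`` restricts template learning to a subset of the labels
    (e.g. the training half) so held-out evaluation never sees test scratches.
    """
    h = calibrate_threshold(
        recording, truth, config.detection,
        target_capture=config.evaluate.target_capture,
    )
    det = replace(config.detection, threshold_h=h)
    islands = find_candidate_islands(recording, det)
    labels = label_islands(islands, truth, config.evaluate.min_overlap_s)
    template = learn_template(recording, template_from or truth, det)
    features = featurize_islands(islands, recording, template, det, config.features)
    return PreparedCorpus(
        recording=recording, truth=truth, threshold_h=h, islands=islands,
        labels=labels, template=template, features=features,
        config=replace(config, detection=det),
    )


def split_half(
    corpus: PreparedCorpus, split_s: float | None = None
) -> tuple[np.ndarray, np.ndarray, LabelTrack, LabelTrack]:
    """Train/test split at ``split_s`` (default: mid-recording) by island
    midpoint; truth bouts are assigned by their own midpoints."""
    if split_s is None:
        split_s = corpus.recording.duration_s / 2.0
    mids = np.asarray([isl.midpoint_s for isl in corpus.islands])
    train_idx = np.flatnonzero(mids < split_s)
    test_idx = np.flatnonzero(mids >= split_s)
    truth_train = LabelTrack(
        [iv for iv in corpus.truth
         if 0.5 * (iv.onset_s + iv.offset_s) < split_s])
    truth_test = LabelTrack(
        [iv for iv in corpus.truth
         if 0.5 * (iv.onset_s + iv.offset_s) >= split_s])
    return train_idx, test_idx, truth_train, truth_test


def _subset(seq, idx):
    return [seq[i] for i in idx]


def _truth_covered(
    islands: list[CandidateIsland], truth: LabelTrack, min_overlap_s: float
) -> LabelTrack:
    """Truth bouts reachable by at least one island in the set (the
    denominator when evaluation is restricted to a subsample)."""
    kept = []
    for iv in truth.scratch_intervals():
        for isl in islands:
            if min(isl.end_s, iv.offset_s) - max(isl.start_s, iv.onset_s) \
                    > min_overlap_s:
                kept.append(iv)
                break
    return LabelTrack(kept)


def holdout_tradeoff(
    corpus: PreparedCorpus,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    truth_test: LabelTrack,
    seed: int,
    n_trees: int | None = None,
    adjust: bool = False,
) -> tuple[list[TradeoffPoint], ForestModel, list[Prediction]]:
    """Train on one island subset, sweep cutoffs on another."""
    cfg = corpus.config
    model = train_forest(
        _subset(corpus.features, train_idx),
        corpus.labels[train_idx],
        n_trees=n_trees or cfg.classify.n_trees,
        seed=seed,
        template=corpus.template,
        max_features=cfg.classify.max_features,
    )
    test_islands = _subset(corpus.islands, test_idx)
    preds = predict(model, _subset(corpus.features, test_idx), test_islands)
    if adjust:
        preds = neighborhood_adjust(
            preds, test_islands, cfg.classify.neighborhood_radius_s)
    curve = tradeoff_curve(
        preds, test_islands, truth_test,
        use_adjusted=adjust, min_overlap_s=cfg.evaluate.min_overlap_s,
    )
    return curve, model, preds


def oob_tradeoff(
    corpus: PreparedCorpus,
    idx: np.ndarray,
    seed: int,
    n_trees: int | None = None,
    restrict_truth: bool = True,
) -> list[TradeoffPoint]:
    """Out-of-bag tradeoff curve on an island subset.

    When ``restrict_truth`` is set, sensitivity is measured against the truth
    bouts the subset can still reach (subsampling removes positive islands,
    and with them any chance of detecting their bouts).
    """
    cfg = corpus.config
    islands = _subset(corpus.islands, idx)
    model = train_forest(
        _subset(corpus.features, idx), corpus.labels[idx],
        n_trees=n_trees or cfg.classify.n_trees, seed=seed,
        template=corpus.template, max_features=cfg.classify.max_features,
    )
    preds = predict_oob(model, _subset(corpus.features, idx), islands)
    truth = (_truth_covered(islands, corpus.truth, cfg.evaluate.min_overlap_s)
             if restrict_truth else corpus.truth)
    return tradeoff_curve(
        preds, islands, truth, min_overlap_s=cfg.evaluate.min_overlap_s)


def operating_point(
    points: list[TradeoffPoint], max_fdr: float = 0.25
) -> TradeoffPoint:
    """The point of maximal sensitivity among those with FDR <= ``max_fdr``
    (ties broken toward lower FDR); falls back to the minimum-FDR point when
    none qualifies."""
    ok = [p for p in points if p.fdr <= max_fdr]
    if not ok:
        return min(points, key=lambda p: p.fdr)
    return max(ok, key=lambda p: (p.sensitivity, -p.fdr))
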