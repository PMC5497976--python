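"""Second pass: random-forest classification of candidate islands.

The forest is a bootstrap-bagged decision-tree ensemble; a prediction for an
island is the fraction of trees voting "scratch". Two prediction protocols
are provided:

* :func:`predict_oob` — honest within-recording accuracy: an island's
  probability counts votes only from trees whose bootstrap bag excluded it.
* :func:`predict` — plain all-tree voting for cross-recording prediction.

:func:`neighborhood_adjust` exploits the temporal clustering of scratch
bouts: an island's probability is multiplied by the mean raw probability of
all other islands whose midpoints lie within 7.5 s. Because a training
island's own label leaks into its neighbors' OOB votes, adjustment should
only be evaluated under train/test on separate recordings — the adjusted
protocol and OOB are mutually exclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .features import FeatureVector, TemplateSpectrum, feature_frame
from .islands import CandidateIsland

__all__ = [
    "ForestModel",
    "Prediction",
    "train_forest",
    "predict_oob",
    "predict",
    "neighborhood_adjust",
    "classify_at_cutoff",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1

DEFAULT_N_TREES = 500


@dataclass
class ForestModel:
    """A fitted forest plus the bookkeeping the evaluation protocol needs."""

    forest: RandomForestClassifier
    bag_membership: list[np.ndarray]  # per tree: sorted unique in-bag row indices
    training_island_ids: np.ndarray
    feature_names: list[str]
    template: TemplateSpectrum | None
    seed: int
    config: dict = field(default_factory=dict)

    @property
    def n_trees(self) -> int:
        return len(self.forest.estimators_)


@dataclass
class Prediction:
    """Predicted scratch probability for one island."""

    island_id: int
    raw_prob: float
    time_s: float
    adjusted_prob: float | None = None

    @property
    def prob(self) -> float:
        return self.raw_prob

    def probability(self, use_adjusted: bool) -> float:
        if use_adjusted:
            if self.adjusted_prob is None:
                raise ValueError("no adjusted probability computed")
            return self.adjusted_prob
        return self.raw_prob


def _as_matrix(
    features: list[FeatureVector] | pd.DataFrame, names: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if isinstance(features, pd.DataFrame):
        frame = features
    else:
        frame = feature_frame(features)
    if names is not None:
        if list(frame.columns) != list(names):
            raise ValueError("feature names do not match the trained model")
    return frame.to_numpy(), frame.index.to_numpy(), list(frame.columns)


def train_forest(
    features: list[FeatureVector] | pd.DataFrame,
    labels: np.ndarray,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    template: TemplateSpectrum | None = None,
    max_features: str | int = "sqrt",
) -> ForestModel:
    """Fit a bootstrap-bagged forest on labeled islands.

    Each tree trains on a bootstrap sample of size n; the rows each tree saw
    are recorded so out-of-bag voting can be reproduced exactly. Deterministic
    for a fixed seed (single-threaded fit).
    """
    X, ids, names = _as_matrix(features)
    y = np.asarray(labels, dtype=int)
    if len(y) != len(X):
        raise ValueError("labels and features must align")
    if len(np.unique(y)) < 2:
        raise ValueError("training requires islands of both classes")
    for cls in (0, 1):
        if np.sum(y == cls) < 2:
            raise ValueError(f"need at least 2 islands of class {cls}")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=max_features,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    bags = [np.unique(s) for s in forest.estimators_samples_]
    oob_counts = np.zeros(len(X), dtype=int)
    for bag in bags:
        mask = np.ones(len(X), dtype=bool)
        mask[bag] = False
        oob_counts[mask] += 1
    if np.any(oob_counts == 0):
        warnings.warn(
            f"{int(np.sum(oob_counts == 0))} islands are in every tree's bag; "
            "their out-of-bag probability is undefined"
        )
    return ForestModel(
        forest=forest,
        bag_membership=bags,
        training_island_ids=ids,
        feature_names=names,
        template=template,
        seed=seed,
        config={"n_trees": n_trees, "max_features": max_features},
    )


def _scratch_votes(model: ForestModel, X: np.ndarray) -> np.ndarray:
    """Per-tree binary votes (trees x rows)."""
    idx_scratch = int(np.flatnonzero(model.forest.classes_ == 1)[0])
    votes = np.empty((model.n_trees, len(X)), dtype=np.int8)
    for t, tree in enumerate(model.forest.estimators_):
        votes[t] = (tree.predict(X) == model.forest.classes_[idx_scratch])
    return votes


def predict_oob(
    model: ForestModel,
    features: list[FeatureVector] | pd.DataFrame,
    islands: list[CandidateIsland] | None = None,
) -> list[Prediction]:
    """Out-of-bag probabilities on the training set.

    For each island, the probability is the fraction of scratch votes among
    trees whose bag excluded it. Features must be exactly the training set
    (checked by island id). Islands that appear in every bag get probability
    NaN and a warning; they should be excluded from evaluation.
    """
    X, ids, _ = _as_matrix(features, model.feature_names)
    if len(ids) != len(model.training_island_ids) or np.any(
        ids != model.training_island_ids
    ):
        raise ValueError("out-of-bag prediction requires the exact training set")
    votes = _scratch_votes(model, X)
    in_bag = np.zeros((model.n_trees, len(X)), dtype=bool)
    for t, bag in enumerate(model.bag_membership):
        in_bag[t, bag] = True
    oob = ~in_bag
    n_oob = oob.sum(axis=0)
    with np.errstate(invalid="ignore"):
        probs = np.where(n_oob > 0, (votes * oob).sum(axis=0) / n_oob, np.nan)
    if np.any(n_oob == 0):
        warnings.warn("some islands have no out-of-bag trees; probability NaN")
    times = _midpoints(ids, islands)
    return [
        Prediction(island_id=int(i), raw_prob=float(p), time_s=float(tm))
        for i, p, tm in zip(ids, probs, times)
    ]


def predict(
    model: ForestModel,
    features: list[FeatureVector] | pd.DataFrame,
    islands: list[CandidateIsland] | None = None,
) -> list[Prediction]:
    """All-tree vote-fraction probabilities (for data the model never saw)."""
    if (isinstance(features, pd.DataFrame) and len(features) == 0) or (
        not isinstance(features, pd.DataFrame) and not features
    ):
        return []
    X, ids, _ = _as_matrix(features, model.feature_names)
    votes = _scratch_votes(model, X)
    probs = votes.mean(axis=0)
    times = _midpoints(ids, islands)
    return [
        Prediction(island_id=int(i), raw_prob=float(p), time_s=float(tm))
        for i, p, tm in zip(ids, probs, times)
    ]


def _midpoints(ids: np.ndarray, islands: list[CandidateIsland] | None) -> np.ndarray:
    if islands is None:
        return np.full(len(ids), np.nan)
    by_id = {isl.island_id: isl.midpoint_s for isl in islands}
    return np.asarray([by_id.get(int(i), np.nan) for i in ids])


def neighborhood_adjust(
    predictions: list[Prediction],
    islands: list[CandidateIsland],
    radius_s: float = 7.5,
) -> list[Prediction]:
    """Multiply each raw probability by the mean raw probability of all other
    islands whose midpoints lie within ``radius_s``.

    Islands with no neighbor keep their raw probability. A single pass on the
    raw probabilities (no iteration), so the result never exceeds the raw
    value.
    """
    by_id = {isl.island_id: isl for isl in islands}
    mids = np.asarray([by_id[p.island_id].midpoint_s for p in predictions])
    raws = np.asarray([p.raw_prob for p in predictions])
    out: list[Prediction] = []
    for i, p in enumerate(predictions):
        near = np.abs(mids - mids[i]) <= radius_s
        near[i] = False
        adjusted = p.raw_prob * float(np.mean(raws[near])) if near.any() else p.raw_prob
        out.append(Prediction(
            island_id=p.island_id, raw_prob=p.raw_prob, time_s=p.time_s,
            adjusted_prob=adjusted,
        ))
    return out


def classify_at_cutoff(
    predictions: list[Prediction], cutoff: float, use_adjusted: bool = False
) -> np.ndarray:
    """Binary labels: scratch iff probability > cutoff."""
    if not 0 <= cutoff <= 1:
        raise ValueError("cutoff must be in [0, 1]")
    return np.asarray(
        [p.probability(use_adjusted) > cutoff for p in predictions], dtype=bool
    )


def save_model(model: ForestModel, path) -> None:
    """Persist the model (ensemble, bags, template, config, seed) to one file."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "forest": model.forest,
        "bag_membership": model.bag_membership,
        "training_island_ids": model.training_island_ids,
        "feature_names": model.feature_names,
        "template": (
            None if model.template is None
            else {"freqs_hz": model.template.freqs_hz,
                  "mean_magnitude": model.template.mean_magnitude}
        ),
        "seed": model.seed,
        "config": model.config,
    }
    joblib.dump(payload, path)


def load_model(path) -> ForestModel:
    """Inverse of :func:`save_model`; rejects unknown format versions."""
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ValueError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ValueError(f"{path} is not a scratchdetect model file")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format {payload['format_version']} unsupported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    tmpl = payload["template"]
    template = None if tmpl is None else TemplateSpectrum(
        freqs_hz=tmpl["freqs_hz"], mean_magnitude=tmpl["mean_magnitude"])
    return ForestModel(
        forest=payload["forest"],
        bag_membership=payload["bag_membership"],
        training_island_ids=payload["training_island_ids"],
        feature_names=payload["feature_names"],
        template=template,
        seed=payload["seed"],
        config=payload["config"],
    )
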