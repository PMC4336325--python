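"""Ensemble consensus of species-distribution-model projections.

Distribution models are evaluated by repeated 70/30 split AUC and their
projections combined into a consensus suitability layer using rank-based
geometric weights: the weight of the r-th best model is proportional to
``decay**(1 - r)`` (decay 1.6 by default), normalized to sum to 1. Across
climate-model / emission-scenario layers an unweighted mean is used.

The distribution models themselves are out of scope; any object with
``fit(X, y)`` and ``score_samples(X)`` plugs in. A simple logistic
suitability learner is included as harness plumbing only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Protocol, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from ._rng import substream

__all__ = [
    "UndefinedAUCError",
    "ModelProjection",
    "LogisticSuitabilityLearner",
    "auc",
    "cross_validate_auc",
    "ensemble_weights",
    "consensus_projection",
    "combine_climate_layers",
]


class UndefinedAUCError(ValueError):
    """AUC is undefined when labels contain a single class."""


class SuitabilityLearner(Protocol):
    def fit(self, X: np.ndarray, y: np.ndarray) -> "SuitabilityLearner": ...
    def score_samples(self, X: np.ndarray) -> np.ndarray: ...


@dataclass
class ModelProjection:
    """One model's suitability layer plus its cross-validated skill."""

    model_id: str
    suitability: pd.Series  # cell_id -> value in [0, 1]
    mean_auc: float

    def __post_init__(self) -> None:
        self.suitability = pd.Series(self.suitability, dtype=float)
        vals = self.suitability.to_numpy()
        if (vals < -1e-12).any() or (vals > 1 + 1e-12).any():
            raise ValueError(f"{self.model_id}: suitability outside [0, 1]")
        if not (0.0 <= self.mean_auc <= 1.0):
            raise ValueError(f"{self.model_id}: mean_auc outside [0, 1]")


class LogisticSuitabilityLearner:
    """Plug-in logistic presence/absence learner (harness plumbing).

    A deliberately simple stand-in for a real distribution model, used to
    exercise the evaluation/consensus machinery; swap in anything satisfying
    the fit/score_samples protocol.
    """

    def __init__(self, **kwargs):
        kwargs.setdefault("max_iter", 1000)
        self._model = LogisticRegression(**kwargs)

    def fit(self, X, y):
        self._model.fit(np.asarray(X), np.asarray(y))
        return self

    def score_samples(self, X):
        return self._model.predict_proba(np.asarray(X))[:, 1]


def auc(scores, labels) -> float:
    """Area under the ROC curve.

    Equals the probability that a random presence outranks a random absence,
    ties counted 1/2 — and is therefore invariant under strictly increasing
    transforms of the scores.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise UndefinedAUCError("labels must contain both presences and absences")
    return float(roc_auc_score(labels, scores))


def cross_validate_auc(
    learner_factory,
    X,
    y,
    seed: int,
    train_frac: float = 0.70,
    replicates: int = 5,
    max_retries: int = 20,
) -> tuple[float, object]:
    """Repeated-split evaluation of a suitability learner.

    Calibrates on a random ``train_frac`` subset and scores AUC on the
    remainder, ``replicates`` times; returns the arithmetic mean AUC together
    with the learner refit on 100% of the data (the fit used for projection).
    Splits whose test half is single-class are retried on the next random
    substream, up to ``max_retries`` attempts per replicate.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    n_train = int(round(train_frac * n))
    if n_train < 1 or n_train >= n:
        raise ValueError("dataset too small for the requested train fraction")
    aucs = []
    counter = 0
    for _ in range(replicates):
        for attempt in range(max_retries):
            rng = substream(seed, "cv-split", counter)
            counter += 1
            perm = rng.permutation(n)
            tr, te = perm[:n_train], perm[n_train:]
            if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
                continue
            model = learner_factory().fit(X[tr], y[tr])
            aucs.append(auc(model.score_samples(X[te]), y[te]))
            break
        else:
            raise UndefinedAUCError(
                f"could not draw a two-class test split in {max_retries} attempts"
            )
    full = learner_factory().fit(X, y)
    return float(np.mean(aucs)), full


def ensemble_weights(n_models: int, decay: float = 1.6) -> np.ndarray:
    """Rank-based geometric consensus weights.

    ``w_r proportional to decay**(1 - r)`` for ranks r = 1..n_models,
    normalized to sum to 1; strictly decreasing in rank whenever decay > 1.
    Weights are used at full precision — rounding to two decimals is a
    reporting convention only.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    if decay < 1.0:
        raise ValueError("decay must be >= 1")
    raw = decay ** (1.0 - np.arange(1, n_models + 1, dtype=float))
    return raw / raw.sum()


def consensus_projection(
    projections: Sequence[ModelProjection],
    decay: float = 1.6,
) -> pd.Series:
    """Skill-weighted consensus of per-model suitability layers.

    Models are ranked by mean AUC (descending; ties broken stably by
    model_id) and combined per cell with :func:`ensemble_weights`. All
    projections must cover the identical cell set.
    """
    if not projections:
        raise ValueError("at least one projection is required")
    cells = set(projections[0].suitability.index)
    for p in projections[1:]:
        if set(p.suitability.index) != cells:
            raise ValueError(f"projection {p.model_id} covers a different cell set")
    ranked = sorted(projections, key=lambda p: (-p.mean_auc, p.model_id))
    w = ensemble_weights(len(ranked), decay)
    index = projections[0].suitability.index
    out = sum(wi * p.suitability.reindex(index) for wi, p in zip(w, ranked))
    out.name = "consensus"
    return out


def combine_climate_layers(layers: Sequence[Mapping | pd.Series]) -> pd.Series:
    """Unweighted mean across climate-model / emission-scenario layers."""
    if not layers:
        raise ValueError("at least one layer is required")
    frames = [pd.Series(l, dtype=float) for l in layers]
    df = pd.concat(frames, axis=1)
    if df.isna().any().any():
        raise ValueError("layers do not share a common cell set")
    return df.mean(axis=1)


def ensemble_forecast(
    layers: Mapping[str, Sequence[ModelProjection]],
    decay: float = 1.6,
    order: str = "sdm_first",
) -> pd.Series:
    """Full consensus across models and climate layers.

    ``layers`` maps a climate-model/emission-scenario layer name to that
    layer's per-SDM projections. With ``order="sdm_first"`` (default) the
    skill-weighted SDM consensus is taken within each layer and the layers
    then averaged unweighted; ``order="layers_first"`` averages each model
    across layers first (its skill averaged too) and weights afterwards.
    The two orders agree exactly when model ranks are shared across layers.
    """
    if order not in ("sdm_first", "layers_first"):
        raise ValueError(f"unknown order {order!r}")
    if order == "sdm_first":
        return combine_climate_layers(
            [consensus_projection(projs, decay) for projs in layers.values()]
        )
    by_model: dict[str, list[ModelProjection]] = {}
    for projs in layers.values():
        for p in projs:
            by_model.setdefault(p.model_id, []).append(p)
    merged = [
        ModelProjection(
            model_id=m,
            suitability=combine_climate_layers([p.suitability for p in ps]),
            mean_auc=float(np.mean([p.mean_auc for p in ps])),
        )
        for m, ps in by_model.items()
    ]
    return consensus_projection(merged, decay)
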