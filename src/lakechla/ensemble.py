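"""Ensemble-of-trees chlorophyll models (regression and binomial).

Two models share one feature encoding: a regression forest predicting Chla
(ug/L) and a classification forest predicting exceedance of the 25 ug/L
eutrophication threshold. Trees are grown unpruned on bootstrap resamples
with a random predictor subset (mtry) considered at each split; aggregation
is by averaging (regression) or majority vote (classification). Backed by
scikit-learn's RandomForestRegressor / RandomForestClassifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .data import FEATURE_NAMES, NormStats

_PERSIST_VERSION = 1

MODES = ("regression", "classification")


@dataclass(frozen=True)
class ForestHyperparams:
    """Forest settings; None means the mode-dependent classical default.

    mtry defaults to floor(p/3) (>=1) for regression and floor(sqrt(p)) for
    classification; min_node_size (minimum terminal-node size) to 5 and 1.
    """

    n_trees: int = 500
    mtry: int | None = None
    min_node_size: int | None = None
    rng_seed: int = 0

    def resolved(self, mode: str, p: int) -> tuple[int, int, int]:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if mode == "regression":
            mtry = self.mtry if self.mtry is not None else max(1, p // 3)
            node = self.min_node_size if self.min_node_size is not None else 5
        else:
            mtry = self.mtry if self.mtry is not None else max(1, int(math.isqrt(p)))
            node = self.min_node_size if self.min_node_size is not None else 1
        if not (1 <= mtry <= p):
            raise ValueError(f"mtry must lie in [1, {p}], got {mtry}")
        return self.n_trees, mtry, node


@dataclass
class EnsembleModel:
    """A fitted forest plus the encoding state needed to use it."""

    mode: str
    estimator: RandomForestRegressor | RandomForestClassifier
    hyperparams: ForestHyperparams
    norm: NormStats | None
    feature_names: tuple[str, ...] = FEATURE_NAMES
    y_range: tuple[float, float] | None = None  # training response range (regression)


def fit_forest(
    features: np.ndarray | Sequence[Sequence[float]],
    response: np.ndarray | Sequence[float],
    mode: str = "regression",
    hyperparams: ForestHyperparams | None = None,
    norm: NormStats | None = None,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
) -> EnsembleModel:
    """Fit a bootstrap-aggregated tree ensemble; deterministic given rng_seed."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    hyperparams = hyperparams or ForestHyperparams()
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D array of uniform-length rows")
    n, p = X.shape
    if n < 10:
        raise ValueError(f"need at least 10 training rows, got {n}")
    n_trees, mtry, node = hyperparams.resolved(mode, p)

    if mode == "regression":
        if np.asarray(response).dtype == bool:
            raise ValueError("boolean response passed to regression mode")
        y = np.asarray(response, dtype=float)
        est: RandomForestRegressor | RandomForestClassifier = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=mtry,
            min_samples_leaf=node,
            bootstrap=True,
            random_state=hyperparams.rng_seed,
            n_jobs=1,
        )
        est.fit(X, y)
        y_range = (float(np.min(y)), float(np.max(y)))
    else:
        y = np.asarray(response)
        if y.dtype != bool:
            if not set(np.unique(y)) <= {0, 1, True, False}:
                raise ValueError("classification response must be boolean")
            y = y.astype(bool)
        if len(np.unique(y)) < 2:
            raise ValueError("classification training data must contain both classes")
        est = RandomForestClassifier(
            n_estimators=n_trees,
            max_features=mtry,
            min_samples_leaf=node,
            bootstrap=True,
            random_state=hyperparams.rng_seed,
            n_jobs=1,
        )
        est.fit(X, y)
        y_range = None
    return EnsembleModel(
        mode=mode,
        estimator=est,
        hyperparams=hyperparams,
        norm=norm,
        feature_names=tuple(feature_names),
        y_range=y_range,
    )


def predict_forest(
    model: EnsembleModel, features: np.ndarray | Sequence[Sequence[float]]
):
    """Predictions of a fitted ensemble.

    Regression: array of mean-of-trees Chla predictions. Classification:
    (labels, vote_fractions) where the label is True iff the eutrophic vote
    fraction strictly exceeds 0.5 (ties break to "not eutrophic").
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != len(model.feature_names):
        raise ValueError(
            f"feature length {X.shape[1]} != training length {len(model.feature_names)}"
        )
    if model.mode == "regression":
        return model.estimator.predict(X)
    proba = model.estimator.predict_proba(X)
    classes = list(model.estimator.classes_)
    if True in classes:
        frac = proba[:, classes.index(True)]
    else:  # pragma: no cover - guarded at fit time
        frac = np.zeros(X.shape[0])
    return frac > 0.5, frac


def save_model(model: EnsembleModel, path: str | Path) -> None:
    """Persist a fitted model (versioned metadata + estimator)."""
    payload = {
        "format_version": _PERSIST_VERSION,
        "mode": model.mode,
        "hyperparams": model.hyperparams,
        "norm": model.norm,
        "feature_names": model.feature_names,
        "y_range": model.y_range,
        "estimator": model.estimator,
    }
    joblib.dump(payload, path)


def load_model(
    path: str | Path, expected_feature_names: tuple[str, ...] | None = FEATURE_NAMES
) -> EnsembleModel:
    """Load a persisted model, checking format version and feature order."""
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != _PERSIST_VERSION:
        raise ValueError(f"unsupported model format version {version!r}")
    names = tuple(payload["feature_names"])
    if expected_feature_names is not None and names != tuple(expected_feature_names):
        raise ValueError(
            f"persisted feature order {names} does not match expected "
            f"{tuple(expected_feature_names)}"
        )
    return EnsembleModel(
        mode=payload["mode"],
        estimator=payload["estimator"],
        hyperparams=payload["hyperparams"],
        norm=payload["norm"],
        feature_names=names,
        y_range=payload["y_range"],
    )
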