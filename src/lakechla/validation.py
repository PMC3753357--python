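"""Repeated-holdout evaluation: averaged R-squared and Cohen's kappa.

The protocol fits both chlorophyll models on a random 80% of the data and
scores predictions on the held-out 20%, repeating 30 times and averaging.
The continuous model is scored with R² between observed and predicted values
and the binomial (>25 ug/L) model with Cohen's kappa. Splitting is by lake
by default, so a lake's four seasonal observations never straddle the
train/test boundary; normalisation statistics are recomputed on each
training split to avoid leakage.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data import (
    EUTROPHIC_THRESHOLD,
    LakeRecord,
    Observation,
    build_feature_matrix,
    compute_norm_stats,
)
from .ensemble import ForestHyperparams, fit_forest, predict_forest

logger = logging.getLogger(__name__)


def r_squared(
    observed: Sequence[float], predicted: Sequence[float], kind: str = "correlation"
) -> float:
    """R² between observed and predicted values.

    ``kind="correlation"`` (default, the reported statistic): squared Pearson
    correlation, which lies in [0, 1] and is invariant to affine rescaling of
    the predictions. ``kind="sse"``: 1 - SSE/SST, which penalises bias.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or obs.size < 3:
        raise ValueError("observed/predicted must be equal-length 1-D, length >= 3")
    if np.var(obs) == 0 or np.var(pred) == 0:
        raise ValueError("zero variance in observed or predicted values")
    if kind == "correlation":
        r = np.corrcoef(obs, pred)[0, 1]
        return float(r * r)
    if kind == "sse":
        sst = float(np.sum((obs - obs.mean()) ** 2))
        sse = float(np.sum((obs - pred) ** 2))
        return 1.0 - sse / sst
    raise ValueError(f"unknown R² kind {kind!r}")


def cohens_kappa(labels_true: Sequence[bool], labels_pred: Sequence[bool]) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    p_o is the observed agreement rate and p_e the chance agreement implied
    by the two marginal label frequencies. When p_e = 1 (both raters
    constant), kappa is defined as 1 for perfect agreement and 0 otherwise.
    """
    t = np.asarray(labels_true, dtype=bool)
    p = np.asarray(labels_pred, dtype=bool)
    if t.shape != p.shape or t.ndim != 1 or t.size < 1:
        raise ValueError("label vectors must be equal-length 1-D, length >= 1")
    n = t.size
    p_o = float(np.mean(t == p))
    pt = float(np.mean(t))
    pp = float(np.mean(p))
    p_e = pt * pp + (1.0 - pt) * (1.0 - pp)
    if math.isclose(p_e, 1.0):
        return 1.0 if math.isclose(p_o, 1.0) else 0.0
    return (p_o - p_e) / (1.0 - p_e)


@dataclass
class ValidationReport:
    """Per-repeat and averaged holdout scores."""

    r2_per_repeat: list[float]
    kappa_per_repeat: list[float]  # NaN where the test split was degenerate
    n_repeats: int
    train_frac: float
    split_unit: str
    rng_seed: int
    r2_kind: str = "correlation"
    pooled: bool = False

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.r2_per_repeat))

    @property
    def mean_kappa(self) -> float:
        vals = [k for k in self.kappa_per_repeat if not math.isnan(k)]
        return float(np.mean(vals)) if vals else float("nan")

    def to_dict(self) -> dict:
        return {
            "n_repeats": self.n_repeats,
            "train_frac": self.train_frac,
            "split_unit": self.split_unit,
            "rng_seed": self.rng_seed,
            "r2_kind": self.r2_kind,
            "pooled": self.pooled,
            "mean_r2": self.mean_r2,
            "mean_kappa": self.mean_kappa,
            "r2_per_repeat": self.r2_per_repeat,
            "kappa_per_repeat": self.kappa_per_repeat,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def per_repeat_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "repeat": np.arange(1, self.n_repeats + 1),
                "r2": self.r2_per_repeat,
                "kappa": self.kappa_per_repeat,
            }
        )

    def summary_text(self) -> str:
        return (
            f"Repeated holdout validation ({self.n_repeats} repeats, "
            f"{self.train_frac:.0%} train, split by {self.split_unit})\n"
            f"  mean R^2   (continuous model): {self.mean_r2:.3f}\n"
            f"  mean kappa (binomial model):   {self.mean_kappa:.3f}\n"
        )


def repeated_holdout(
    records: Sequence[LakeRecord],
    observations: Sequence[Observation],
    hyperparams: ForestHyperparams | None = None,
    train_frac: float = 0.8,
    n_repeats: int = 30,
    split_unit: str = "lake",
    rng_seed: int = 0,
    threshold: float = EUTROPHIC_THRESHOLD,
    r2_kind: str = "correlation",
    pooled: bool = False,
) -> ValidationReport:
    """Run the repeated 80/20 holdout protocol on a dataset.

    Per repeat: draw the split, compute normalisation statistics on the
    training rows only, fit the regression and classification forests,
    predict the test rows, and record R² and kappa. A test split with a
    single exceedance class yields a missing kappa for that repeat (excluded
    from the average, logged). ``pooled=True`` scores one R²/kappa over the
    pooled test predictions of all repeats instead of averaging per-repeat
    statistics.
    """
    if not (0.0 < train_frac < 1.0):
        raise ValueError("train_frac must lie in (0, 1)")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if split_unit not in ("lake", "observation"):
        raise ValueError("split_unit must be 'lake' or 'observation'")
    hyperparams = hyperparams or ForestHyperparams()
    rng = np.random.default_rng(rng_seed)
    obs_arr = list(observations)
    chla = np.array([o.chla for o in obs_arr])
    labels = chla > threshold

    r2s: list[float] = []
    kappas: list[float] = []
    pool_obs: list[float] = []
    pool_pred: list[float] = []
    pool_true: list[bool] = []
    pool_lab: list[bool] = []
    for rep in range(n_repeats):
        if split_unit == "lake":
            ids = [r.lake_id for r in records]
            perm = rng.permutation(len(ids))
            n_train = max(1, round(train_frac * len(ids)))
            train_ids = {ids[i] for i in perm[:n_train]}
            train_mask = np.array([o.lake_id in train_ids for o in obs_arr])
        else:
            perm = rng.permutation(len(obs_arr))
            n_train = max(1, round(train_frac * len(obs_arr)))
            train_mask = np.zeros(len(obs_arr), dtype=bool)
            train_mask[perm[:n_train]] = True
        test_mask = ~train_mask
        if test_mask.sum() < 3:
            raise ValueError("test split too small; use a larger dataset")

        train_obs = [o for o, m in zip(obs_arr, train_mask) if m]
        test_obs = [o for o, m in zip(obs_arr, test_mask) if m]
        norm = compute_norm_stats(records, train_obs)
        X_train = build_feature_matrix(records, train_obs, norm)
        X_test = build_feature_matrix(records, test_obs, norm)
        y_train = chla[train_mask]
        y_test = chla[test_mask]
        lab_train = labels[train_mask]
        lab_test = labels[test_mask]

        seed = int(rng.integers(0, 2**31 - 1))
        reg = fit_forest(X_train, y_train, "regression",
                         ForestHyperparams(hyperparams.n_trees, hyperparams.mtry,
                                           hyperparams.min_node_size, seed), norm)
        pred = predict_forest(reg, X_test)
        r2s.append(r_squared(y_test, pred, kind=r2_kind))
        pool_obs.extend(y_test)
        pool_pred.extend(pred)

        if len(np.unique(lab_train)) < 2:
            logger.warning("repeat %d: single-class training split, kappa missing", rep + 1)
            kappas.append(float("nan"))
            continue
        clf = fit_forest(X_train, lab_train, "classification",
                         ForestHyperparams(hyperparams.n_trees, hyperparams.mtry,
                                           hyperparams.min_node_size, seed), norm)
        lab_pred, _ = predict_forest(clf, X_test)
        if len(np.unique(lab_test)) < 2:
            logger.warning("repeat %d: single-class test split, kappa missing", rep + 1)
            kappas.append(float("nan"))
        else:
            kappas.append(cohens_kappa(lab_test, lab_pred))
        pool_true.extend(lab_test)
        pool_lab.extend(lab_pred)

    if pooled:
        pooled_r2 = r_squared(pool_obs, pool_pred, kind=r2_kind)
        pooled_kappa = cohens_kappa(pool_true, pool_lab) if pool_true else float("nan")
        return ValidationReport(
            r2_per_repeat=[pooled_r2],
            kappa_per_repeat=[pooled_kappa],
            n_repeats=n_repeats,
            train_frac=train_frac,
            split_unit=split_unit,
            rng_seed=rng_seed,
            r2_kind=r2_kind,
            pooled=True,
        )
    return ValidationReport(
        r2_per_repeat=r2s,
        kappa_per_repeat=kappas,
        n_repeats=n_repeats,
        train_frac=train_frac,
        split_unit=split_unit,
        rng_seed=rng_seed,
        r2_kind=r2_kind,
    )
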