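"""Model / Results front-end tying the pipeline together.

``LakeChlaModel`` holds a lake-catchment dataset and the forest settings;
``fit()`` returns a ``LakeChlaResults`` carrying both fitted forests (the
continuous and the binomial chlorophyll model), from which validation,
scenario grids, contrasts and the policy projection are run::

    model = LakeChlaModel.from_csv("lakes.csv")
    res = model.fit(seed=1)
    print(res.summary())
    report = res.validate(n_repeats=30, seed=1)
    policy = res.policy_scenario()
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import scenario as _scenario
from .data import (
    EUTROPHIC_THRESHOLD,
    LakeRecord,
    Observation,
    build_feature_matrix,
    compute_norm_stats,
    frame_to_records,
    read_lake_table,
    validate_records,
)
from .ensemble import EnsembleModel, ForestHyperparams, fit_forest, predict_forest
from .validation import ValidationReport, r_squared, repeated_holdout


class LakeChlaModel:
    """Random-forest chlorophyll model of a lake population.

    Parameters
    ----------
    records, observations
        The lake-catchment dataset (one record per lake, four seasonal
        chlorophyll observations per lake).
    hyperparams
        Forest settings shared by the regression and classification models.
    threshold
        Chla level (ug/L) above which an observation counts as eutrophic.
    """

    def __init__(
        self,
        records: Sequence[LakeRecord],
        observations: Sequence[Observation],
        hyperparams: ForestHyperparams | None = None,
        threshold: float = EUTROPHIC_THRESHOLD,
        strict: bool = True,
    ) -> None:
        violations = [v for v in validate_records(records, observations) if v.severity == "error"]
        if violations and strict:
            head = "; ".join(f"{v.lake_id}:{v.field} ({v.rule})" for v in violations[:5])
            raise ValueError(f"{len(violations)} invariant violation(s): {head}")
        self.records = list(records)
        self.observations = list(observations)
        self.hyperparams = hyperparams or ForestHyperparams()
        self.threshold = threshold

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, hyperparams: ForestHyperparams | None = None, **kwargs
    ) -> "LakeChlaModel":
        records, observations = frame_to_records(df)
        return cls(records, observations, hyperparams=hyperparams, **kwargs)

    @classmethod
    def from_csv(
        cls, path: str | Path, hyperparams: ForestHyperparams | None = None, **kwargs
    ) -> "LakeChlaModel":
        records, observations = read_lake_table(path)
        return cls(records, observations, hyperparams=hyperparams, **kwargs)

    def fit(self, seed: int | None = None) -> "LakeChlaResults":
        """Fit both forests on the full dataset and return the results."""
        hp = self.hyperparams
        if seed is not None:
            hp = ForestHyperparams(hp.n_trees, hp.mtry, hp.min_node_size, seed)
        norm = compute_norm_stats(self.records, self.observations)
        X = build_feature_matrix(self.records, self.observations, norm)
        y = np.array([o.chla for o in self.observations])
        labels = y > self.threshold
        regressor = fit_forest(X, y, "regression", hp, norm)
        classifier = fit_forest(X, labels, "classification", hp, norm)
        return LakeChlaResults(self, regressor, classifier, X, y)

    def validate(
        self,
        n_repeats: int = 30,
        train_frac: float = 0.8,
        split_unit: str = "lake",
        seed: int = 0,
        **kwargs,
    ) -> ValidationReport:
        """Repeated-holdout evaluation (refits inside each repeat)."""
        return repeated_holdout(
            self.records,
            self.observations,
            hyperparams=self.hyperparams,
            train_frac=train_frac,
            n_repeats=n_repeats,
            split_unit=split_unit,
            rng_seed=seed,
            threshold=self.threshold,
            **kwargs,
        )


@dataclass
class LakeChlaResults:
    """Fitted chlorophyll forests and everything computed from them."""

    model: LakeChlaModel
    regressor: EnsembleModel
    classifier: EnsembleModel
    exog: np.ndarray
    endog: np.ndarray

    @property
    def fittedvalues(self) -> np.ndarray:
        return predict_forest(self.regressor, self.exog)

    @property
    def resid(self) -> np.ndarray:
        return self.endog - self.fittedvalues

    def validate(self, **kwargs) -> ValidationReport:
        return self.model.validate(**kwargs)

    def scenario_grid(
        self,
        m_s_axis: Sequence[float] = _scenario.DEFAULT_AXIS,
        m_li_axis: Sequence[float] = _scenario.DEFAULT_AXIS,
        frequency_from: str = "regression",
    ) -> _scenario.ScenarioGrid:
        return _scenario.evaluate_grid(
            self.regressor,
            self.classifier,
            self.model.records,
            m_s_axis=m_s_axis,
            m_li_axis=m_li_axis,
            threshold=self.model.threshold,
            frequency_from=frequency_from,
        )

    def policy_scenario(
        self,
        multipliers: tuple[float, float] = _scenario.POLICY_2030,
        frequency_from: str = "regression",
    ) -> _scenario.PolicyScenarioReport:
        return _scenario.policy_scenario_2030(
            self.regressor,
            self.classifier,
            self.model.records,
            self.model.observations,
            multipliers=multipliers,
            threshold=self.model.threshold,
            frequency_from=frequency_from,
        )

    def delta_contrast(self) -> list[_scenario.DeltaContrast]:
        return _scenario.delta_chla_contrast(self.regressor, self.model.records)

    def summary(self) -> str:
        """Human-readable fit summary (in-sample; see validate() for holdout)."""
        n_lakes = len(self.model.records)
        n_obs = len(self.model.observations)
        n_drain = sum(r.connectivity == "drainage" for r in self.model.records)
        fitted = self.fittedvalues
        r2 = r_squared(self.endog, fitted)
        frac = 100.0 * np.mean(self.endog > self.model.threshold)
        hp = self.regressor.hyperparams
        lines = [
            "Lake chlorophyll-a random-forest model",
            "=" * 46,
            f"lakes: {n_lakes} ({n_drain} drainage, {n_lakes - n_drain} seepage); "
            f"observations: {n_obs}",
            f"forests: {hp.n_trees} trees, seed {hp.rng_seed}",
            f"in-sample R^2 (squared correlation): {r2:.3f}",
            f"observed % of values > {self.model.threshold:g} ug/L: {frac:.1f}",
        ]
        return "\n".join(lines) + "\n"
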