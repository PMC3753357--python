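"""Pressure-scenario projection: multiplier grids, curve shapes, thresholds.

Two catchment-scale pressures are scanned from a hypothetical zero-impact
state (multiplier 0) to twice the current state (2): nutrient loads via the
catchment:lake area ratio S, and population density via the impervious land
cover LI. When LI is rescaled the remaining cover is redistributed between
agriculture (LA) and forest (LF) keeping their ratio constant, so the
composition always closes to 100%.

For every grid cell the fitted models predict all lake x season
combinations; cells aggregate mean Chla and the frequency of predictions
above the 25 ug/L eutrophication threshold, for the whole population and
for the drainage / seepage strata separately. On top of the grid sit the
analyses used for management questions: response-curve shape (linear vs
saturating), the load reduction needed for recovery, the LI increase that
cancels a load reduction, and the 2030 policy scenario (-30% loads, +20%
impervious cover).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .data import (
    EUTROPHIC_THRESHOLD,
    PREDICTORS,
    SEASONS,
    LakeRecord,
    NormStats,
    Observation,
)
from .ensemble import EnsembleModel, predict_forest

logger = logging.getLogger(__name__)

STRATA = ("all", "drainage", "seepage")

DEFAULT_AXIS = tuple(np.round(np.arange(0.0, 2.0 + 1e-9, 0.02), 10))

#: 2030 policy scenario: loads -30%, impervious cover +20%
POLICY_2030 = (0.70, 1.20)


@dataclass(frozen=True)
class PressureMultipliers:
    """Scenario multipliers; (1, 1) is the identity (current state)."""

    m_S: float = 1.0
    m_LI: float = 1.0

    def __post_init__(self) -> None:
        if self.m_S < 0 or self.m_LI < 0:
            raise ValueError("pressure multipliers must be >= 0")


def rebalance_landcover(
    li0: float, la0: float, lf0: float, m_li: float, fallback_ratio: float = 0.5
) -> tuple[float, float, float]:
    """Rescale impervious cover and close the composition to 100%.

    li = min(m_li * li0, 100); the remainder is split between LA and LF in
    their original ratio (or by ``fallback_ratio`` as the LA share when
    la0 + lf0 = 0).
    """
    if m_li < 0:
        raise ValueError("m_li must be >= 0")
    if abs(li0 + la0 + lf0 - 100.0) > 1e-6:
        raise ValueError(f"land cover must sum to 100, got {li0 + la0 + lf0}")
    li = min(m_li * li0, 100.0)
    remainder = 100.0 - li
    denom = la0 + lf0
    if denom > 0:
        la = remainder * la0 / denom
    else:
        la = remainder * fallback_ratio
    lf = remainder - la
    return li, la, lf


def apply_multipliers(record: LakeRecord, m: PressureMultipliers) -> LakeRecord:
    """Scenario transform of a lake: S scaled, land cover rebalanced."""
    li, la, lf = rebalance_landcover(record.li_pct, record.la_pct, record.lf_pct, m.m_LI)
    return dataclasses.replace(
        record, s_ratio=m.m_S * record.s_ratio, li_pct=li, la_pct=la, lf_pct=lf
    )


def percent_change(baseline: float, scenario: float) -> float:
    """100 * (scenario - baseline) / baseline."""
    if baseline == 0:
        raise ValueError("percent change undefined for zero baseline")
    return 100.0 * (scenario - baseline) / baseline


# ---------------------------------------------------------------------------
# scenario grid


@dataclass
class ScenarioGrid:
    """Per-cell, per-stratum aggregates over the multiplier grid.

    ``mean_chla[stratum]`` and ``pct_eutrophic[stratum]`` are arrays of shape
    (len(m_s_axis), len(m_li_axis)); frequencies are percentages in [0, 100].
    """

    m_s_axis: tuple[float, ...]
    m_li_axis: tuple[float, ...]
    mean_chla: dict[str, np.ndarray]
    pct_eutrophic: dict[str, np.ndarray]
    threshold: float = EUTROPHIC_THRESHOLD

    def _axis_index(self, axis: Sequence[float], value: float) -> int:
        arr = np.asarray(axis)
        hits = np.flatnonzero(np.isclose(arr, value, atol=1e-9))
        if hits.size == 0:
            raise ValueError(f"value {value} is not on the grid axis (no interpolation)")
        return int(hits[0])

    def cell(self, m_s: float, m_li: float, stratum: str = "all") -> tuple[float, float]:
        i = self._axis_index(self.m_s_axis, m_s)
        j = self._axis_index(self.m_li_axis, m_li)
        return float(self.mean_chla[stratum][i, j]), float(self.pct_eutrophic[stratum][i, j])

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for stratum in self.mean_chla:
            for i, ms in enumerate(self.m_s_axis):
                for j, ml in enumerate(self.m_li_axis):
                    rows.append(
                        {
                            "m_s": ms,
                            "m_li": ml,
                            "stratum": stratum,
                            "mean_chla": self.mean_chla[stratum][i, j],
                            "pct_eutrophic": self.pct_eutrophic[stratum][i, j],
                        }
                    )
        return pd.DataFrame(rows, columns=["m_s", "m_li", "stratum", "mean_chla", "pct_eutrophic"])


def _scenario_feature_block(
    records: Sequence[LakeRecord],
    norm: NormStats,
    m_s: float,
    m_li: float,
) -> np.ndarray:
    """Vectorised feature matrix for all lake x season rows of one cell.

    Equivalent to apply_multipliers + encode_features per record; rows are
    ordered season-major: all lakes in winter, then spring, etc.
    """
    li0 = np.array([r.li_pct for r in records])
    la0 = np.array([r.la_pct for r in records])
    lf0 = np.array([r.lf_pct for r in records])
    li = np.minimum(m_li * li0, 100.0)
    remainder = 100.0 - li
    denom = la0 + lf0
    with np.errstate(invalid="ignore", divide="ignore"):
        la = np.where(denom > 0, remainder * la0 / denom, remainder * 0.5)
    lf = remainder - la
    cols = {
        "s_ratio": m_s * np.array([r.s_ratio for r in records]),
        "lf_pct": lf,
        "la_pct": la,
        "li_pct": li,
        "drainage_density_Id": np.array([r.drainage_density_Id for r in records]),
        "depth_D": np.array([r.depth_D for r in records]),
        "altitude": np.array([r.altitude for r in records]),
    }
    z = np.column_stack(
        [(cols[name] - mu) / sd for name, mu, sd in zip(PREDICTORS, norm.means, norm.sds)]
    )
    n = len(records)
    blocks = []
    for k in range(len(SEASONS)):
        onehot = np.zeros((n, len(SEASONS)))
        onehot[:, k] = 1.0
        blocks.append(np.hstack([z, onehot]))
    return np.vstack(blocks)


def evaluate_grid(
    reg_model: EnsembleModel,
    clf_model: EnsembleModel | None,
    records: Sequence[LakeRecord],
    m_s_axis: Sequence[float] = DEFAULT_AXIS,
    m_li_axis: Sequence[float] = DEFAULT_AXIS,
    threshold: float = EUTROPHIC_THRESHOLD,
    frequency_from: str = "regression",
) -> ScenarioGrid:
    """Predict every (m_S, m_LI) cell and aggregate per stratum.

    Frequencies come from thresholded regression predictions by default
    (``frequency_from="classification"`` uses the binomial model's votes).
    """
    if frequency_from not in ("regression", "classification"):
        raise ValueError("frequency_from must be 'regression' or 'classification'")
    if frequency_from == "classification" and clf_model is None:
        raise ValueError("classification-model frequencies need clf_model")
    norm = reg_model.norm
    if norm is None:
        raise ValueError("regression model carries no normalisation stats")
    n = len(records)
    conn = np.array([r.connectivity for r in records])
    season_conn = np.tile(conn, len(SEASONS))
    masks = {"all": np.ones(n * len(SEASONS), dtype=bool)}
    for stratum in ("drainage", "seepage"):
        m = season_conn == stratum
        if m.any():
            masks[stratum] = m
        else:
            warnings.warn(f"stratum {stratum!r} is empty; omitted from grid")

    ns, nl = len(m_s_axis), len(m_li_axis)
    mean_chla = {s: np.empty((ns, nl)) for s in masks}
    pct_eu = {s: np.empty((ns, nl)) for s in masks}

    # batch cells into one predict call per m_s row to amortise forest overhead
    for i, m_s in enumerate(m_s_axis):
        X_row = np.vstack(
            [_scenario_feature_block(records, norm, float(m_s), float(m_li)) for m_li in m_li_axis]
        )
        preds = predict_forest(reg_model, X_row)
        if frequency_from == "classification":
            labels, _ = predict_forest(clf_model, X_row)
        else:
            labels = preds > threshold
        preds = preds.reshape(nl, n * len(SEASONS))
        labels = labels.reshape(nl, n * len(SEASONS))
        # 1-D per-cell means keep the (1,1) cell bit-identical to a direct
        # baseline prediction (summation order matters at the ulp level)
        for j in range(nl):
            for stratum, mask in masks.items():
                mean_chla[stratum][i, j] = preds[j][mask].mean()
                pct_eu[stratum][i, j] = 100.0 * labels[j][mask].mean()

    return ScenarioGrid(
        m_s_axis=tuple(float(v) for v in m_s_axis),
        m_li_axis=tuple(float(v) for v in m_li_axis),
        mean_chla=mean_chla,
        pct_eutrophic=pct_eu,
        threshold=threshold,
    )


def mean_response_curve(
    grid: ScenarioGrid,
    varying: str = "m_S",
    fixed_value: float = 1.0,
    stratum: str = "all",
) -> tuple[np.ndarray, np.ndarray]:
    """Grid slice: mean Chla along one multiplier axis at a fixed other axis."""
    if varying not in ("m_S", "m_LI"):
        raise ValueError("varying must be 'm_S' or 'm_LI'")
    if stratum not in grid.mean_chla:
        raise ValueError(f"stratum {stratum!r} not in grid")
    if varying == "m_S":
        j = grid._axis_index(grid.m_li_axis, fixed_value)
        return np.asarray(grid.m_s_axis), grid.mean_chla[stratum][:, j].copy()
    i = grid._axis_index(grid.m_s_axis, fixed_value)
    return np.asarray(grid.m_li_axis), grid.mean_chla[stratum][i, :].copy()


def _aicc(rss: float, n: int, k: int) -> float:
    # k counts mean-function parameters plus the error variance
    if n - k - 1 <= 0:
        return float("inf")
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def characterize_curve_shape(
    multipliers: Sequence[float], values: Sequence[float], aicc_margin: float = 2.0
) -> dict:
    """Classify a response curve as linear or saturating by corrected AIC.

    Fits y = a + b*m and y = y0 + c*m/(k+m) by least squares and compares
    small-sample-corrected AIC. Ties and constant curves resolve to linear,
    the simpler model: following the usual parsimony rule for
    information-criterion selection, "saturating" requires its AICc to beat
    the linear fit by more than ``aicc_margin`` (models within ~2 AICc units
    are equivalent).
    """
    m = np.asarray(multipliers, dtype=float)
    y = np.asarray(values, dtype=float)
    if m.size != y.size or m.size < 5:
        raise ValueError("need >= 5 curve points")
    if not (np.all(np.isfinite(m)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite curve values")
    n = m.size

    a, b = np.polynomial.polynomial.polyfit(m, y, 1)
    rss_lin = float(np.sum((y - (a + b * m)) ** 2))
    aicc_lin = _aicc(rss_lin, n, 3)

    if np.ptp(y) < 1e-12:  # constant curve: simpler model wins outright
        return {
            "shape": "linear",
            "aicc_linear": aicc_lin,
            "aicc_saturating": float("inf"),
            "linear_params": (float(a), float(b)),
            "saturating_params": None,
        }

    def sat(mm, y0, c, k):
        return y0 + c * mm / (k + mm)

    best = None
    for k0 in (0.05, 0.2, 1.0, 5.0):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    sat,
                    m,
                    y,
                    p0=(float(y.min()), float(np.ptp(y)), k0),
                    bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
                    maxfev=20000,
                )
            rss = float(np.sum((y - sat(m, *popt)) ** 2))
            if best is None or rss < best[1]:
                best = (popt, rss)
        except (RuntimeError, ValueError):
            continue

    if best is None:
        aicc_sat = float("inf")
        sat_params = None
    else:
        sat_params = tuple(float(v) for v in best[0])
        aicc_sat = _aicc(best[1], n, 4)

    shape = "saturating" if aicc_sat < aicc_lin - aicc_margin else "linear"
    return {
        "shape": shape,
        "aicc_linear": aicc_lin,
        "aicc_saturating": aicc_sat,
        "linear_params": (float(a), float(b)),
        "saturating_params": sat_params,
    }


# ---------------------------------------------------------------------------
# contrasts and thresholds


@dataclass(frozen=True)
class DeltaContrast:
    """Per-lake Chla contrast between the reduced-LI and increased-LI scenarios.

    delta_chla > 0 means the lake is predicted to be *greener* with all
    impervious cover removed than with it doubled — the counter-intuitive
    branch of the v-shape, expected for small agricultural catchments where
    removed urban cover converts to agriculture.
    """

    lake_id: str
    delta_chla: float
    pressure_index: float  # (LI / max(LA, 1%)) * catchment area (km2)


def delta_chla_contrast(
    reg_model: EnsembleModel, records: Sequence[LakeRecord], la_floor: float = 1.0
) -> list[DeltaContrast]:
    """Season-averaged predicted Chla under m_LI=0 minus under m_LI=2 (m_S=1)."""
    norm = reg_model.norm
    if norm is None:
        raise ValueError("regression model carries no normalisation stats")
    X_red = _scenario_feature_block(records, norm, 1.0, 0.0)
    X_inc = _scenario_feature_block(records, norm, 1.0, 2.0)
    pred_red = predict_forest(reg_model, X_red).reshape(len(SEASONS), len(records))
    pred_inc = predict_forest(reg_model, X_inc).reshape(len(SEASONS), len(records))
    delta = pred_red.mean(axis=0) - pred_inc.mean(axis=0)
    out = []
    for i, r in enumerate(records):
        index = (r.li_pct / max(r.la_pct, la_floor)) * r.catchment_area
        out.append(DeltaContrast(r.lake_id, float(delta[i]), float(index)))
    return out


def find_recovery_threshold(
    grid: ScenarioGrid, stratum: str = "all", target: str = "all_recovered"
) -> float | None:
    """Load reduction (1 - m_S) needed to meet a recovery target at m_LI = 1.

    Scans m_S downward from 1 on the grid; ``all_recovered`` seeks the
    largest m_S with zero eutrophic frequency, ``frequency_halved`` the
    largest m_S with frequency at most half the current-state value.
    Returns None when no grid point qualifies ("not reached").
    """
    if target not in ("all_recovered", "frequency_halved"):
        raise ValueError("target must be 'all_recovered' or 'frequency_halved'")
    j = grid._axis_index(grid.m_li_axis, 1.0)
    ms = np.asarray(grid.m_s_axis)
    freq = grid.pct_eutrophic[stratum][:, j]
    i1 = grid._axis_index(grid.m_s_axis, 1.0)
    baseline = freq[i1]
    goal = 0.0 if target == "all_recovered" else baseline / 2.0
    order = np.argsort(ms)[::-1]  # largest m_S first
    for i in order:
        if ms[i] > 1.0 + 1e-9:
            continue
        if freq[i] <= goal:
            return float(1.0 - ms[i])
    return None


def find_compensation(
    grid: ScenarioGrid,
    stratum: str,
    m_s_fixed: float,
    reference_frequency: float,
) -> float | None:
    """Smallest grid m_LI >= 1 restoring the reference eutrophic frequency.

    At the fixed (reduced) load multiplier, finds the first impervious-cover
    multiplier whose frequency reaches ``reference_frequency``; None when the
    compensation is not reached on the grid.
    """
    i = grid._axis_index(grid.m_s_axis, m_s_fixed)
    ml = np.asarray(grid.m_li_axis)
    freq = grid.pct_eutrophic[stratum][i, :]
    for j in np.argsort(ml):
        if ml[j] < 1.0 - 1e-9:
            continue
        if freq[j] >= reference_frequency:
            return float(ml[j])
    return None


# ---------------------------------------------------------------------------
# policy scenario


@dataclass
class PolicyScenarioReport:
    """Observed state, model baseline and scenario projections per stratum.

    Percent changes compare the scenario against the model baseline at
    multipliers (1, 1), so the model's own bias cancels out of the change.
    """

    multipliers: tuple[float, float]
    threshold: float
    strata: dict[str, dict[str, float]]  # stratum -> row of statistics

    def to_dict(self) -> dict:
        return {
            "multipliers": {"m_S": self.multipliers[0], "m_LI": self.multipliers[1]},
            "threshold": self.threshold,
            "strata": self.strata,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def summary_text(self) -> str:
        lines = [
            f"Policy scenario (m_S = {self.multipliers[0]:.2f}, "
            f"m_LI = {self.multipliers[1]:.2f}; eutrophic if Chla > "
            f"{self.threshold:g} ug/L)",
            f"{'stratum':<10}{'':<16}{'mean Chla':>12}{'% >25 ug/L':>14}",
        ]
        for stratum, row in self.strata.items():
            lines.append(
                f"{stratum:<10}{'observed':<16}{row['observed_mean_chla']:>12.1f}"
                f"{row['observed_pct_eutrophic']:>14.1f}"
            )
            lines.append(
                f"{'':<10}{'model baseline':<16}{row['baseline_mean_chla']:>12.1f}"
                f"{row['baseline_pct_eutrophic']:>14.1f}"
            )
            lines.append(
                f"{'':<10}{'scenario':<16}{row['scenario_mean_chla']:>12.1f}"
                f"{row['scenario_pct_eutrophic']:>14.1f}"
            )
            pc = row["pct_change_mean_chla"]
            pf = row.get("pct_change_pct_eutrophic", float("nan"))
            lines.append(f"{'':<10}{'change':<16}{pc:>11.1f}%{pf:>13.1f}%")
        return "\n".join(lines) + "\n"


def policy_scenario_2030(
    reg_model: EnsembleModel,
    clf_model: EnsembleModel | None,
    records: Sequence[LakeRecord],
    observations: Sequence[Observation],
    multipliers: tuple[float, float] = POLICY_2030,
    threshold: float = EUTROPHIC_THRESHOLD,
    frequency_from: str = "regression",
) -> PolicyScenarioReport:
    """Project the policy scenario and report it against the current state."""
    norm = reg_model.norm
    if norm is None:
        raise ValueError("regression model carries no normalisation stats")
    m_s, m_li = multipliers
    conn = {r.lake_id: r.connectivity for r in records}
    obs_chla = np.array([o.chla for o in observations])
    obs_conn = np.array([conn[o.lake_id] for o in observations])

    season_conn = np.tile(np.array([r.connectivity for r in records]), len(SEASONS))

    def predict_cell(ms: float, ml: float) -> tuple[np.ndarray, np.ndarray]:
        X = _scenario_feature_block(records, norm, ms, ml)
        pred = predict_forest(reg_model, X)
        if frequency_from == "classification":
            if clf_model is None:
                raise ValueError("classification-model frequencies need clf_model")
            labels, _ = predict_forest(clf_model, X)
        else:
            labels = pred > threshold
        return pred, labels

    base_pred, base_lab = predict_cell(1.0, 1.0)
    scen_pred, scen_lab = predict_cell(float(m_s), float(m_li))

    strata: dict[str, dict[str, float]] = {}
    for stratum in STRATA:
        if stratum == "all":
            obs_mask = np.ones(len(observations), dtype=bool)
            mask = np.ones(len(season_conn), dtype=bool)
        else:
            obs_mask = obs_conn == stratum
            mask = season_conn == stratum
        if not mask.any():
            warnings.warn(f"stratum {stratum!r} is empty; omitted from policy report")
            continue
        row = {
            "observed_mean_chla": float(obs_chla[obs_mask].mean()) if obs_mask.any() else float("nan"),
            "observed_pct_eutrophic": float(100.0 * (obs_chla[obs_mask] > threshold).mean())
            if obs_mask.any()
            else float("nan"),
            "baseline_mean_chla": float(base_pred[mask].mean()),
            "baseline_pct_eutrophic": float(100.0 * base_lab[mask].mean()),
            "scenario_mean_chla": float(scen_pred[mask].mean()),
            "scenario_pct_eutrophic": float(100.0 * scen_lab[mask].mean()),
        }
        row["pct_change_mean_chla"] = percent_change(
            row["baseline_mean_chla"], row["scenario_mean_chla"]
        )
        if row["baseline_pct_eutrophic"] != 0:
            row["pct_change_pct_eutrophic"] = percent_change(
                row["baseline_pct_eutrophic"], row["scenario_pct_eutrophic"]
            )
        else:
            row["pct_change_pct_eutrophic"] = float("nan")
        strata[stratum] = row
    return PolicyScenarioReport(
        multipliers=(float(m_s), float(m_li)), threshold=threshold, strata=strata
    )
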