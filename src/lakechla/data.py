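"""Domain types, tabular I/O and trophic-state classification.

The unit of analysis is a lake (or reservoir) described by catchment-scale
descriptors, with four seasonal chlorophyll-a observations. Lakes are either
*drainage* (connected to the stream network, typically a large effective
catchment) or *seepage* (no surface inlet/outlet, fed by runoff and
groundwater).

Predictors, in the fixed model order:

======== ======================================================= =========
symbol   meaning                                                 unit
======== ======================================================= =========
S        catchment area / lake area (nutrient-load proxy)        --
LF       forest cover of the catchment                           %
LA       agricultural cover of the catchment                     %
LI       impervious (urban) cover of the catchment               %
Id       drainage-network density                                km km-2
D        lake mean depth                                         m
altitude altitude of the water body                              m a.s.l.
======== ======================================================= =========

plus a one-hot season indicator (winter, spring, summer, autumn).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SEASONS: tuple[str, ...] = ("winter", "spring", "summer", "autumn")
CONNECTIVITY_CLASSES: tuple[str, ...] = ("drainage", "seepage")

#: numeric predictors in fixed model order: (S, LF, LA, LI, Id, D, altitude)
PREDICTORS: tuple[str, ...] = (
    "s_ratio",
    "lf_pct",
    "la_pct",
    "li_pct",
    "drainage_density_Id",
    "depth_D",
    "altitude",
)

FEATURE_NAMES: tuple[str, ...] = PREDICTORS + tuple(f"season_{s}" for s in SEASONS)

CSV_COLUMNS: tuple[str, ...] = (
    "lake_id",
    "connectivity",
    "lake_area_ha",
    "depth_m",
    "catchment_area_km2",
    "s_ratio",
    "li_pct",
    "la_pct",
    "lf_pct",
    "drainage_density",
    "altitude_m",
    "season",
    "chla_ugL",
)

#: composition must close to 100 % within this tolerance
COMPOSITION_TOL = 1e-6
#: relative band within which stored S must agree with catchment/lake areas
S_RATIO_REL_TOL = 0.05

#: default OECD fixed-boundary annual-mean Chla limits (ug/L):
#: oligotrophic < 2.5 <= mesotrophic <= 8 < eutrophic <= 25 < hypertrophic
OECD_BOUNDARIES: tuple[float, float, float] = (2.5, 8.0, 25.0)

#: Chla threshold (ug/L) above which an observation counts as eutrophic
EUTROPHIC_THRESHOLD = 25.0


class SchemaError(ValueError):
    """Input table does not match the documented CSV schema."""


@dataclass(frozen=True)
class LakeRecord:
    """One lake with its catchment descriptors."""

    lake_id: str
    connectivity: str  # "drainage" | "seepage"
    lake_area: float  # ha
    depth_D: float  # m
    catchment_area: float  # km2
    s_ratio: float  # dimensionless, catchment/lake area
    li_pct: float
    la_pct: float
    lf_pct: float
    drainage_density_Id: float  # km km-2
    altitude: float  # m

    def __post_init__(self) -> None:
        if self.connectivity not in CONNECTIVITY_CLASSES:
            raise ValueError(
                f"connectivity must be one of {CONNECTIVITY_CLASSES}, "
                f"got {self.connectivity!r}"
            )


@dataclass(frozen=True)
class Observation:
    """One lake x season chlorophyll-a measurement (ug/L)."""

    lake_id: str
    season_T: str
    chla: float

    def __post_init__(self) -> None:
        if self.season_T not in SEASONS:
            raise ValueError(f"season must be one of {SEASONS}, got {self.season_T!r}")


@dataclass(frozen=True)
class Violation:
    """A record/observation invariant that does not hold."""

    lake_id: str
    field: str
    rule: str
    severity: str = "error"  # "error" | "warning"


@dataclass(frozen=True)
class NormStats:
    """Per-predictor training mean and standard deviation for z-scoring."""

    means: tuple[float, ...]
    sds: tuple[float, ...]
    predictors: tuple[str, ...] = PREDICTORS

    def __post_init__(self) -> None:
        if len(self.means) != len(self.predictors) or len(self.sds) != len(self.predictors):
            raise ValueError("means/sds length must match predictor count")
        for name, sd in zip(self.predictors, self.sds):
            if not sd > 0:
                raise ValueError(f"predictor {name!r} has non-positive sd (constant?)")


def record_predictor_values(record: LakeRecord) -> np.ndarray:
    """Numeric predictor values of a record, in fixed model order."""
    return np.array([getattr(record, name) for name in PREDICTORS], dtype=float)


def compute_norm_stats(
    records: Sequence[LakeRecord], observations: Sequence[Observation]
) -> NormStats:
    """Training means/sds (sample sd, n-1) over the training observations.

    Statistics are taken over observation rows (lake-level predictors repeated
    once per seasonal observation), matching how the model sees the data.
    Must only ever be called on the training split during validation.
    """
    by_id = {r.lake_id: r for r in records}
    rows = np.array(
        [record_predictor_values(by_id[obs.lake_id]) for obs in observations], dtype=float
    )
    if rows.shape[0] < 2:
        raise ValueError("need at least 2 training rows to compute normalisation stats")
    means = rows.mean(axis=0)
    sds = rows.std(axis=0, ddof=1)
    for name, sd in zip(PREDICTORS, sds):
        if not sd > 0:
            raise ValueError(f"constant predictor {name!r}: cannot z-score")
    return NormStats(means=tuple(means), sds=tuple(sds))


def encode_features(record: LakeRecord, season: str, norm: NormStats) -> np.ndarray:
    """z-scored predictors followed by the one-hot season indicator (length 11)."""
    if season not in SEASONS:
        raise ValueError(f"unknown season {season!r}; expected one of {SEASONS}")
    x = record_predictor_values(record)
    z = (x - np.asarray(norm.means)) / np.asarray(norm.sds)
    onehot = np.array([1.0 if s == season else 0.0 for s in SEASONS])
    out = np.concatenate([z, onehot])
    if not np.all(np.isfinite(out)):
        raise ValueError(f"non-finite feature for lake {record.lake_id!r}")
    return out


def build_feature_matrix(
    records: Sequence[LakeRecord],
    observations: Sequence[Observation],
    norm: NormStats,
) -> np.ndarray:
    """Feature matrix (n_obs x 11) for observation rows, in file order."""
    by_id = {r.lake_id: r for r in records}
    return np.array(
        [encode_features(by_id[o.lake_id], o.season_T, norm) for o in observations]
    )


def classify_eutrophic(chla: float, threshold: float = EUTROPHIC_THRESHOLD) -> bool:
    """True iff chla is strictly greater than the eutrophication threshold."""
    if chla < 0:
        raise ValueError(f"chla must be >= 0, got {chla}")
    return chla > threshold


def oecd_trophic_class(
    annual_mean_chla: float, boundaries: tuple[float, float, float] = OECD_BOUNDARIES
) -> str:
    """OECD fixed-boundary trophic class from annual-mean Chla (ug/L)."""
    if annual_mean_chla < 0:
        raise ValueError("annual mean chla must be >= 0")
    b_oligo, b_meso, b_eu = boundaries
    if annual_mean_chla < b_oligo:
        return "oligotrophic"
    if annual_mean_chla <= b_meso:
        return "mesotrophic"
    if annual_mean_chla <= b_eu:
        return "eutrophic"
    return "hypertrophic"


def validate_records(
    records: Sequence[LakeRecord], observations: Sequence[Observation]
) -> list[Violation]:
    """Check every type invariant; violations are data, not exceptions."""
    out: list[Violation] = []
    for r in records:
        for field in ("lake_area", "depth_D", "catchment_area", "s_ratio"):
            if not getattr(r, field) > 0:
                out.append(Violation(r.lake_id, field, "must be strictly positive"))
        for field in ("li_pct", "la_pct", "lf_pct"):
            v = getattr(r, field)
            if not (0.0 <= v <= 100.0):
                out.append(Violation(r.lake_id, field, "must lie in [0, 100]"))
        comp = r.li_pct + r.la_pct + r.lf_pct
        if abs(comp - 100.0) > COMPOSITION_TOL:
            out.append(
                Violation(r.lake_id, "li_pct+la_pct+lf_pct", f"must sum to 100, got {comp!r}")
            )
        if r.drainage_density_Id < 0:
            out.append(Violation(r.lake_id, "drainage_density_Id", "must be >= 0"))
        # cross-check stored S against the area ratio (1 km2 == 100 ha)
        if r.lake_area > 0 and r.s_ratio > 0 and r.catchment_area > 0:
            implied = r.catchment_area * 100.0 / r.lake_area
            if abs(implied / r.s_ratio - 1.0) > S_RATIO_REL_TOL:
                out.append(
                    Violation(
                        r.lake_id,
                        "s_ratio",
                        f"inconsistent with catchment/lake areas (implied {implied:.4g})",
                        severity="warning",
                    )
                )
    known = {r.lake_id for r in records}
    seen: set[tuple[str, str]] = set()
    for o in observations:
        if o.lake_id not in known:
            out.append(Violation(o.lake_id, "lake_id", "observation references unknown lake"))
        if o.chla < 0:
            out.append(Violation(o.lake_id, "chla", "must be >= 0"))
        key = (o.lake_id, o.season_T)
        if key in seen:
            out.append(Violation(o.lake_id, "season_T", f"duplicate season {o.season_T!r}"))
        seen.add(key)
    return out


def records_to_frame(
    records: Sequence[LakeRecord], observations: Sequence[Observation]
) -> pd.DataFrame:
    """Long-format table: one row per observation, lake fields repeated."""
    by_id = {r.lake_id: r for r in records}
    rows = []
    for o in observations:
        r = by_id[o.lake_id]
        rows.append(
            {
                "lake_id": r.lake_id,
                "connectivity": r.connectivity,
                "lake_area_ha": r.lake_area,
                "depth_m": r.depth_D,
                "catchment_area_km2": r.catchment_area,
                "s_ratio": r.s_ratio,
                "li_pct": r.li_pct,
                "la_pct": r.la_pct,
                "lf_pct": r.lf_pct,
                "drainage_density": r.drainage_density_Id,
                "altitude_m": r.altitude,
                "season": o.season_T,
                "chla_ugL": o.chla,
            }
        )
    return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def frame_to_records(df: pd.DataFrame) -> tuple[list[LakeRecord], list[Observation]]:
    """Parse a long-format table into records and observations (file order)."""
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    numeric_cols = [
        "lake_area_ha",
        "depth_m",
        "catchment_area_km2",
        "s_ratio",
        "li_pct",
        "la_pct",
        "lf_pct",
        "drainage_density",
        "altitude_m",
        "chla_ugL",
    ]
    records: dict[str, LakeRecord] = {}
    observations: list[Observation] = []
    for i, row in enumerate(df.itertuples(index=False)):
        vals = {}
        for c in numeric_cols:
            raw = getattr(row, c)
            try:
                vals[c] = float(raw)
            except (TypeError, ValueError) as exc:
                raise SchemaError(
                    f"non-numeric value {raw!r} in column {c!r} at data row {i + 1}"
                ) from exc
            if math.isnan(vals[c]):
                raise SchemaError(f"missing value in column {c!r} at data row {i + 1}")
        lake_id = str(getattr(row, "lake_id"))
        rec = LakeRecord(
            lake_id=lake_id,
            connectivity=str(getattr(row, "connectivity")),
            lake_area=vals["lake_area_ha"],
            depth_D=vals["depth_m"],
            catchment_area=vals["catchment_area_km2"],
            s_ratio=vals["s_ratio"],
            li_pct=vals["li_pct"],
            la_pct=vals["la_pct"],
            lf_pct=vals["lf_pct"],
            drainage_density_Id=vals["drainage_density"],
            altitude=vals["altitude_m"],
        )
        if lake_id not in records:
            records[lake_id] = rec
        observations.append(Observation(lake_id, str(getattr(row, "season")), vals["chla_ugL"]))
    return list(records.values()), observations


def read_lake_table(path: str | Path) -> tuple[list[LakeRecord], list[Observation]]:
    """Read the long-format lake CSV (dot decimal, UTF-8)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"lake table not found: {path}")
    df = pd.read_csv(path, dtype={"lake_id": str})
    return frame_to_records(df)


def write_lake_table(
    records: Sequence[LakeRecord],
    observations: Sequence[Observation],
    path: str | Path,
) -> None:
    """Write the long-format CSV; round-trips through read_lake_table."""
    df = records_to_frame(records, observations)
    try:
        # repr-precision floats so read(write(x)) round-trips below 1e-9
        df.to_csv(path, index=False, float_format="%.17g")
    except OSError as exc:
        raise OSError(f"failed writing lake table to {path}: {exc}") from exc
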