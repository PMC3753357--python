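"""Synthetic lake-catchment datasets with a known chlorophyll response.

The generator emulates the statistical structure of a 48-lake periurban
survey: two connectivity strata (drainage lakes with large, heavily loaded
catchments; seepage lakes with small ones), log-normally skewed areas,
zero-inflated impervious cover, and four seasonal chlorophyll-a observations
per lake.

The ground-truth response is a saturating (Michaelis-Menten) function of an
effective nutrient-load index built from the catchment:lake area ratio S and
the land covers:

    E[Chla] = A * S' / (S' + K) * s_T * exp(b_lake)
    S'      = S * (1 + g_I * (LI/100) * log10(1 + catchment_km2)**size_scaling
                    + g_A * (LA/100))

A single half-saturation constant K makes the curve saturating at
drainage-typical S (>> K) and near-linear at seepage-typical S (<~ K). The
urban term grows with catchment size, so converting impervious cover to
agriculture *raises* expected Chla in small agricultural catchments and
lowers it in large urbanised ones (the v-shape mechanism). s_T is a seasonal
multiplier, b_lake ~ N(0, sigma_lake^2) a lake-level random effect, and
observations carry multiplicative log-normal noise exp(N(0, sigma_obs^2)).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import (
    SEASONS,
    LakeRecord,
    Observation,
)


@dataclass(frozen=True)
class ClassParams:
    """Stratum-level distribution parameters (drainage or seepage)."""

    lake_area_median: float  # ha
    lake_area_mean: float  # ha
    depth_mean: float  # m
    depth_sd: float  # m
    catchment_median: float  # km2
    catchment_mean: float  # km2
    li_mean: float  # % impervious cover


@dataclass(frozen=True)
class SyntheticConfig:
    """Full generator configuration; defaults reproduce the study strata."""

    n_lakes: int = 48
    p_drainage: float = 25.0 / 48.0
    drainage: ClassParams = field(
        default_factory=lambda: ClassParams(
            lake_area_median=8.8,
            lake_area_mean=18.2,
            depth_mean=2.0,
            depth_sd=0.9,
            catchment_median=29.5,
            catchment_mean=398.7,
            li_mean=19.5,
        )
    )
    seepage: ClassParams = field(
        default_factory=lambda: ClassParams(
            lake_area_median=12.3,
            lake_area_mean=26.5,
            depth_mean=3.3,
            depth_sd=1.4,
            catchment_median=0.3,
            catchment_mean=1.4,
            li_mean=11.8,
        )
    )
    depth_floor: float = 0.5  # m
    #: rank correlation of log lake area and log catchment area within a
    #: stratum (larger lakes drain larger catchments); tempers the spread of
    #: the emergent S = catchment/lake ratio while preserving both marginals
    area_correlation: float = 0.7
    li_zero_prob: float = 0.15  # point mass at LI = 0
    li_beta_conc: float = 3.0  # Beta concentration of the nonzero LI draw
    la_share_alpha: float = 2.0  # Beta(a, b) split of non-urban land into LA
    la_share_beta: float = 2.0
    id_median: float = 1.0  # km km-2, log-normal median of drainage density
    id_sigma: float = 0.5
    altitude_range: tuple[float, float] = (30.0, 180.0)
    # ground-truth response parameters
    chla_scale_A: float = 51.0  # ug/L, asymptotic Chla at full load saturation
    half_saturation_K: float = 60.0  # load index at half the asymptote
    gamma_impervious: float = 0.8
    gamma_agricultural: float = 0.6
    size_scaling: float = 1.0  # exponent on log10(1 + catchment area)
    season_multipliers: tuple[float, float, float, float] = (0.5, 1.0, 1.7, 1.2)
    sigma_lake: float = 0.3
    sigma_obs: float = 0.4
    rng_seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.p_drainage <= 1.0 and 0.0 <= self.li_zero_prob <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_lakes < 0:
            raise ValueError("n_lakes must be >= 0")
        if not self.half_saturation_K > 0:
            raise ValueError("half_saturation_K must be > 0")
        if self.sigma_lake < 0 or self.sigma_obs < 0:
            raise ValueError("noise sds must be >= 0")
        if any(m <= 0 for m in self.season_multipliers):
            raise ValueError("season multipliers must be > 0")
        if not (-1.0 <= self.area_correlation <= 1.0):
            raise ValueError("area_correlation must lie in [-1, 1]")
        for name, cp in (("drainage", self.drainage), ("seepage", self.seepage)):
            for what, med, mean in (
                ("lake_area", cp.lake_area_median, cp.lake_area_mean),
                ("catchment", cp.catchment_median, cp.catchment_mean),
            ):
                if mean < med:
                    raise ValueError(
                        f"{name} {what}: mean {mean} < median {med} is infeasible "
                        "for a log-normal target"
                    )

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticConfig":
        raw = json.loads(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SyntheticConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = dict(raw)
        for cls_field in ("drainage", "seepage"):
            if cls_field in kwargs and isinstance(kwargs[cls_field], dict):
                kwargs[cls_field] = ClassParams(**kwargs[cls_field])
        for tup in ("season_multipliers", "altitude_range"):
            if tup in kwargs:
                kwargs[tup] = tuple(kwargs[tup])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class GroundTruth:
    """Latent generative state: per-lake random effects and load indices."""

    lake_ids: tuple[str, ...]
    lake_effects: tuple[float, ...]  # b_lake, log scale
    load_index: tuple[float, ...]  # S' per lake
    expected_chla: dict[str, tuple[float, float, float, float]]  # per season, pre-noise


def lognormal_params(median: float, mean: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given median and mean.

    median = exp(mu); mean = exp(mu + sigma^2/2)  =>  sigma^2 = 2 ln(mean/median).
    """
    if median <= 0 or mean < median:
        raise ValueError(f"infeasible log-normal target: median={median}, mean={mean}")
    return math.log(median), math.sqrt(2.0 * math.log(mean / median))


def load_index(record: LakeRecord, config: SyntheticConfig) -> float:
    """Effective nutrient-load index S' of a lake."""
    size_term = math.log10(1.0 + record.catchment_area) ** config.size_scaling
    factor = (
        1.0
        + config.gamma_impervious * (record.li_pct / 100.0) * size_term
        + config.gamma_agricultural * (record.la_pct / 100.0)
    )
    return record.s_ratio * factor

def saturating(load: float, K: float) -> float:
    """Michaelis-Menten saturation term S'/(S'+K)."""
    return load / (load + K)


def true_response(
    record: LakeRecord,
    season: str,
    config: SyntheticConfig,
    lake_effect: float = 0.0,
) -> float:
    """Expected Chla (ug/L) of a lake in a season, before observation noise."""
    if season not in SEASONS:
        raise ValueError(f"unknown season {season!r}")
    s_t = config.season_multipliers[SEASONS.index(season)]
    sp = load_index(record, config)
    return config.chla_scale_A * saturating(sp, config.half_saturation_K) * s_t * math.exp(
        lake_effect
    )


def generate_lakes(
    config: SyntheticConfig | None = None,
) -> tuple[list[LakeRecord], list[Observation], GroundTruth]:
    """Draw a reproducible synthetic dataset under the configured strata."""
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_lakes

    is_drainage = rng.random(n) < config.p_drainage
    records: list[LakeRecord] = []
    for i in range(n):
        cp = config.drainage if is_drainage[i] else config.seepage
        mu_l, sig_l = lognormal_params(cp.lake_area_median, cp.lake_area_mean)
        mu_c, sig_c = lognormal_params(cp.catchment_median, cp.catchment_mean)
        # Gaussian copula between log areas; marginals stay Table-1 matched
        rho = config.area_correlation
        z_l = rng.standard_normal()
        z_c = rho * z_l + math.sqrt(1.0 - rho * rho) * rng.standard_normal()
        lake_area = float(np.exp(mu_l + sig_l * z_l))
        catchment = float(np.exp(mu_c + sig_c * z_c))
        # truncated normal depth, floored at depth_floor
        a = (config.depth_floor - cp.depth_mean) / cp.depth_sd
        depth = float(
            stats.truncnorm.ppf(rng.random(), a, np.inf, loc=cp.depth_mean, scale=cp.depth_sd)
        )
        s_ratio = catchment * 100.0 / lake_area
        if rng.random() < config.li_zero_prob:
            li = 0.0
        else:
            # conditional mean so the stratum mean matches cp.li_mean
            mu_li = min(cp.li_mean / (100.0 * (1.0 - config.li_zero_prob)), 0.95)
            a_b = mu_li * config.li_beta_conc
            b_b = (1.0 - mu_li) * config.li_beta_conc
            li = float(np.clip(100.0 * rng.beta(a_b, b_b), 0.0, 100.0))
        la_share = float(rng.beta(config.la_share_alpha, config.la_share_beta))
        la = (100.0 - li) * la_share
        lf = 100.0 - li - la
        drainage_density = float(
            rng.lognormal(math.log(config.id_median), config.id_sigma)
        )
        altitude = float(rng.uniform(*config.altitude_range))
        records.append(
            LakeRecord(
                lake_id=f"L{i + 1:04d}",
                connectivity="drainage" if is_drainage[i] else "seepage",
                lake_area=lake_area,
                depth_D=depth,
                catchment_area=catchment,
                s_ratio=s_ratio,
                li_pct=li,
                la_pct=la,
                lf_pct=lf,
                drainage_density_Id=drainage_density,
                altitude=altitude,
            )
        )

    lake_effects = rng.normal(0.0, config.sigma_lake, size=n)
    observations: list[Observation] = []
    expected: dict[str, tuple[float, float, float, float]] = {}
    loads = []
    for i, rec in enumerate(records):
        loads.append(load_index(rec, config))
        per_season = []
        for season in SEASONS:
            mu = true_response(rec, season, config, lake_effect=float(lake_effects[i]))
            per_season.append(mu)
            chla = mu * float(np.exp(rng.normal(0.0, config.sigma_obs)))
            observations.append(Observation(rec.lake_id, season, chla))
        expected[rec.lake_id] = tuple(per_season)  # type: ignore[arg-type]

    truth = GroundTruth(
        lake_ids=tuple(r.lake_id for r in records),
        lake_effects=tuple(float(b) for b in lake_effects),
        load_index=tuple(loads),
        expected_chla=expected,
    )
    return records, observations, truth


def calibration_report(
    records: Sequence[LakeRecord], observations: Sequence[Observation]
) -> pd.DataFrame:
    """Per-stratum summary for comparison against the study's printed stats.

    One row per connectivity class with lake-level means/medians, mean Chla
    over observations and the fraction of observations above 25 ug/L.
    """
    if not records:
        return pd.DataFrame()
    rec_df = pd.DataFrame(
        {
            "connectivity": [r.connectivity for r in records],
            "lake_area_ha": [r.lake_area for r in records],
            "depth_m": [r.depth_D for r in records],
            "catchment_area_km2": [r.catchment_area for r in records],
            "s_ratio": [r.s_ratio for r in records],
            "li_pct": [r.li_pct for r in records],
        }
    )
    by_id = {r.lake_id: r.connectivity for r in records}
    obs_df = pd.DataFrame(
        {
            "connectivity": [by_id[o.lake_id] for o in observations],
            "chla": [o.chla for o in observations],
        }
    )
    rows = []
    for cls, grp in rec_df.groupby("connectivity"):
        obs = obs_df[obs_df["connectivity"] == cls]["chla"]
        row: dict[str, float | str] = {"connectivity": cls, "n_lakes": len(grp)}
        for col in ("lake_area_ha", "depth_m", "catchment_area_km2", "s_ratio", "li_pct"):
            row[f"{col}_mean"] = grp[col].mean()
            row[f"{col}_median"] = grp[col].median()
        row["chla_mean"] = obs.mean() if len(obs) else float("nan")
        row["frac_over_25"] = (obs > 25.0).mean() if len(obs) else float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("connectivity")
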