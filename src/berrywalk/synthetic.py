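"""Seeded synthetic agroecosystem datasets with a known yield surface.

The generator emulates the structure of the boreal lowbush-blueberry
fertilizer-trial dataset the pipeline targets: ~1500 observations from
three sites, N-P-K doses in the trial ranges (0-90 / 0-39 / 0-75 kg/ha),
log-normal leaf and soil test concentrations, acidic pH (4.0-5.6), daily
boreal weather for every site-year plus the six preceding years, and berry
yields in 600-13800 kg/ha.

The ground-truth response is linear in the 6-year historical stage weather
indices and concave quadratic in the controllable block (leaf balances,
soil balances, pH, doses) around a known optimum, plus Gaussian noise.
Weather effects dominate, dose effects are small — so investigative-model
coefficient ordering, surrogate error and optimizer recovery are all
testable against the generating truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compositions import (
    LEAF_KAPPA,
    SOIL_KAPPA,
    ilr,
    leaf_partition,
    soil_partition,
    with_filling_value,
)
from .features import DOSE_COLUMNS, assemble_features
from .weather import default_stage_windows

__all__ = ["SyntheticConfig", "GroundTruth", "generate_dataset", "true_yield"]

_SITES = ("site_A", "site_B", "site_C")

#: leaf concentration log-medians, g/kg (B and Al are trace elements)
_LEAF_MEDIANS = {
    "leaf_N": 17.0,
    "leaf_P": 1.2,
    "leaf_K": 5.0,
    "leaf_Ca": 4.2,
    "leaf_Mg": 1.6,
    "leaf_B": 28.0,  # mg/kg
    "leaf_Al": 50.0,  # mg/kg
}
#: soil Mehlich-3 log-medians, mg/kg
_SOIL_MEDIANS = {"soil_P": 45.0, "soil_K": 55.0, "soil_Ca": 320.0, "soil_Mg": 45.0}


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic generator."""

    n_obs: int = 1504
    sites: tuple[str, ...] = _SITES
    years: tuple[int, int] = (2008, 2011)  # inclusive bearing years
    dose_ranges: dict = field(
        default_factory=lambda: {"N": (0.0, 90.0), "P": (0.0, 39.0), "K": (0.0, 75.0)}
    )
    leaf_log_sd: float = 0.18
    soil_log_sd: float = 0.35
    ph_range: tuple[float, float] = (4.0, 5.6)
    noise_sd: float = 1000.0
    yield_bounds: tuple[float, float] = (600.0, 13800.0)
    # boreal weather archetype
    temp_annual_mean: float = 2.5
    temp_amplitude: float = 16.0
    temp_peak_doy: int = 201
    site_temp_offsets: tuple[float, ...] = (-0.8, 0.0, 0.9)
    year_temp_sd: float = 0.8
    daily_temp_sd: float = 3.0
    wet_day_prob: float = 0.45
    precip_shape: float = 1.2
    precip_scale: float = 5.0
    site_precip_factors: tuple[float, ...] = (0.9, 1.0, 1.15)
    year_precip_log_sd: float = 0.15

    def __post_init__(self) -> None:
        if self.n_obs < 1:
            raise ValueError("n_obs must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name, (lo, hi) in self.dose_ranges.items():
            if not lo < hi:
                raise ValueError(f"invalid dose range for {name}: ({lo}, {hi})")
        if not self.ph_range[0] < self.ph_range[1]:
            raise ValueError("invalid pH range")


@dataclass
class GroundTruth:
    """The generating response surface (pre-noise, pre-clip)."""

    baseline: float
    weather_coef: dict[str, float]
    weather_ref: dict[str, float]
    leaf_bstar: np.ndarray
    soil_bstar: np.ndarray
    leaf_curvature: np.ndarray  # positive penalties per leaf balance
    soil_curvature: np.ndarray
    ph_opt: float
    ph_curvature: float
    dose_opt: dict[str, float]
    dose_curvature: dict[str, float]
    leaf_balance_names: list[str] = field(default_factory=list)
    soil_balance_names: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "baseline": self.baseline,
            "weather_coef": self.weather_coef,
            "weather_ref": self.weather_ref,
            "leaf_bstar": np.asarray(self.leaf_bstar).tolist(),
            "soil_bstar": np.asarray(self.soil_bstar).tolist(),
            "leaf_curvature": np.asarray(self.leaf_curvature).tolist(),
            "soil_curvature": np.asarray(self.soil_curvature).tolist(),
            "ph_opt": self.ph_opt,
            "ph_curvature": self.ph_curvature,
            "dose_opt": self.dose_opt,
            "dose_curvature": self.dose_curvature,
            "leaf_balance_names": self.leaf_balance_names,
            "soil_balance_names": self.soil_balance_names,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        d = dict(d)
        for key in ("leaf_bstar", "soil_bstar", "leaf_curvature", "soil_curvature"):
            d[key] = np.asarray(d[key], dtype=float)
        return cls(**d)


def _default_ground_truth() -> GroundTruth:
    leaf, soil = leaf_partition(), soil_partition()
    windows = default_stage_windows()
    # leaf/soil optima: balances of the median test composition
    leaf_median = with_filling_value(
        [v * (1e-3 if k in ("leaf_B", "leaf_Al") else 1.0) for k, v in _LEAF_MEDIANS.items()],
        [k.removeprefix("leaf_") for k in _LEAF_MEDIANS],
        LEAF_KAPPA,
    )
    soil_median = with_filling_value(
        list(_SOIL_MEDIANS.values()),
        [k.removeprefix("soil_") for k in _SOIL_MEDIANS],
        SOIL_KAPPA,
    )
    temp_coef = [250.0, 300.0, -150.0, 200.0, 350.0]  # kg/ha per degC
    precip_coef = [3.0, -2.0, 5.0, 2.0, -3.0]  # kg/ha per mm
    temp_ref = [2.7, 10.3, 16.2, 18.2, 16.4]  # degC, boreal stage means
    precip_ref = [92.0, 103.0, 46.0, 108.0, 65.0]  # mm per stage
    weather_coef, weather_ref = {}, {}
    for w, tc, pc, tr, pr in zip(windows, temp_coef, precip_coef, temp_ref, precip_ref):
        weather_coef[f"hist {w.name}_mean_temp"] = tc
        weather_ref[f"hist {w.name}_mean_temp"] = tr
        weather_coef[f"hist {w.name}_total_precip"] = pc
        weather_ref[f"hist {w.name}_total_precip"] = pr
    return GroundTruth(
        baseline=7000.0,
        weather_coef=weather_coef,
        weather_ref=weather_ref,
        leaf_bstar=ilr(leaf_median, leaf),
        soil_bstar=ilr(soil_median, soil),
        leaf_curvature=np.full(7, 5000.0),
        soil_curvature=np.full(4, 1100.0),
        ph_opt=4.6,
        ph_curvature=600.0,
        dose_opt={"N": 55.0, "P": 20.0, "K": 35.0},
        dose_curvature={"N": 0.02, "P": 0.08, "K": 0.03},
        leaf_balance_names=[f"leaf {n}" for n in leaf.balance_names()],
        soil_balance_names=[f"soil {n}" for n in soil.balance_names()],
    )


def true_yield(features: pd.DataFrame | pd.Series, gt: GroundTruth) -> np.ndarray:
    """Deterministic ground-truth yield (kg/ha) at the given feature rows.

    Raises ``KeyError`` naming the first missing feature column.
    """
    df = features.to_frame().T if isinstance(features, pd.Series) else features
    for name in (
        list(gt.weather_coef)
        + gt.leaf_balance_names
        + gt.soil_balance_names
        + ["pH"]
        + DOSE_COLUMNS
    ):
        if name not in df.columns:
            raise KeyError(f"missing feature {name!r}")
    y = np.full(len(df), gt.baseline, dtype=float)
    for name, coef in gt.weather_coef.items():
        y += coef * (df[name].to_numpy(dtype=float) - gt.weather_ref[name])
    leaf_b = df[gt.leaf_balance_names].to_numpy(dtype=float)
    soil_b = df[gt.soil_balance_names].to_numpy(dtype=float)
    y -= ((leaf_b - gt.leaf_bstar) ** 2 * gt.leaf_curvature).sum(axis=1)
    y -= ((soil_b - gt.soil_bstar) ** 2 * gt.soil_curvature).sum(axis=1)
    y -= gt.ph_curvature * (df["pH"].to_numpy(dtype=float) - gt.ph_opt) ** 2
    for nut in ("N", "P", "K"):
        d = df[f"dose_{nut}"].to_numpy(dtype=float)
        y -= gt.dose_curvature[nut] * (d - gt.dose_opt[nut]) ** 2
    return y


def _generate_weather(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Daily boreal weather for every site from first_year-7 to last_year."""
    first, last = config.years
    frames = []
    for i, site in enumerate(config.sites):
        t_off = config.site_temp_offsets[i % len(config.site_temp_offsets)]
        p_fac = config.site_precip_factors[i % len(config.site_precip_factors)]
        for year in range(first - 7, last + 1):
            dates = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
            doy = dates.dayofyear.to_numpy()
            year_t = rng.normal(0.0, config.year_temp_sd)
            year_p = float(np.exp(rng.normal(0.0, config.year_precip_log_sd)))
            seasonal = config.temp_annual_mean + config.temp_amplitude * np.cos(
                2 * np.pi * (doy - config.temp_peak_doy) / 365.25
            )
            tmean = seasonal + t_off + year_t + rng.normal(0, config.daily_temp_sd, doy.size)
            spread_lo = rng.uniform(2.0, 6.0, doy.size)
            spread_hi = rng.uniform(2.0, 6.0, doy.size)
            wet = rng.random(doy.size) < config.wet_day_prob
            amount = rng.gamma(config.precip_shape, config.precip_scale, doy.size)
            precip = np.where(wet, amount * p_fac * year_p, 0.0)
            frames.append(
                pd.DataFrame(
                    {
                        "site": site,
                        "date": dates,
                        "tmean": np.round(tmean, 2),
                        "tmin": np.round(tmean - spread_lo, 2),
                        "tmax": np.round(tmean + spread_hi, 2),
                        "precip": np.round(precip, 2),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def generate_dataset(
    config: SyntheticConfig | None = None,
    seed: int = 0,
    ground_truth: GroundTruth | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (observations, daily weather, ground truth), seeded.

    Yields are ``clip(true_yield + N(0, noise_sd^2), yield_bounds)``; the
    historical weather features entering the truth are computed with the
    same code the downstream pipeline uses.
    """
    config = config or SyntheticConfig()
    gt = ground_truth or _default_ground_truth()
    rng = np.random.default_rng(seed)
    weather_df = _generate_weather(config, rng)

    n = config.n_obs
    first, last = config.years
    obs = pd.DataFrame(
        {
            "site": rng.choice(config.sites, size=n),
            "year": rng.integers(first, last + 1, size=n),
        }
    )
    for nut in ("N", "P", "K"):
        lo, hi = config.dose_ranges[nut]
        obs[f"dose_{nut}"] = np.round(rng.uniform(lo, hi, size=n), 1)
    for col, med in _LEAF_MEDIANS.items():
        obs[col] = np.round(
            med * np.exp(rng.normal(0.0, config.leaf_log_sd, size=n)), 3
        )
    for col, med in _SOIL_MEDIANS.items():
        obs[col] = np.round(
            med * np.exp(rng.normal(0.0, config.soil_log_sd, size=n)), 2
        )
    obs["pH"] = np.round(rng.uniform(*config.ph_range, size=n), 2)

    feats = assemble_features(obs, weather_df)
    y = true_yield(feats, gt)
    if config.noise_sd > 0:
        y = y + rng.normal(0.0, config.noise_sd, size=n)
    obs["yield"] = np.round(np.clip(y, *config.yield_bounds), 1)
    return obs, weather_df, gt
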