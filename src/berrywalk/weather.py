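"""Daily weather records to seasonal and phenological-stage yield features.

Lowbush blueberry phenology in the boreal production region is tracked over
five calendar windows (Julian days) from flower-bud opening to harvest.
Daily station records (mean/min/max temperature, total precipitation) are
aggregated per window into mean temperature, total precipitation, freezing
days (daily mean strictly below -5 degC) and growing degree-days above a
4.4 degC base accumulated from April 1 (day of year 91). Predictive models
see only the past, so the historical variant averages each window's indices
over the six years (three crop cycles) preceding the season of observation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StageWindow",
    "default_stage_windows",
    "season_window",
    "freezing_days",
    "gdd",
    "stage_features",
    "historical_features",
    "GDD_BASE",
    "GDD_START_DAY",
    "FREEZING_THRESHOLD",
]

logger = logging.getLogger(__name__)

GDD_BASE = 4.4
GDD_START_DAY = 91
FREEZING_THRESHOLD = -5.0

REQUIRED_COLUMNS = ("date", "tmean", "precip")


@dataclass(frozen=True)
class StageWindow:
    """An inclusive Julian-day window named after a phenological stage."""

    name: str
    start_day: int
    end_day: int

    def __post_init__(self) -> None:
        if not (1 <= self.start_day <= self.end_day <= 366):
            raise ValueError(
                f"invalid window [{self.start_day}, {self.end_day}]"
            )

    def contains(self, day_of_year: int) -> bool:
        return self.start_day <= day_of_year <= self.end_day


def default_stage_windows() -> list[StageWindow]:
    """The five phenological stages of lowbush blueberry (Julian days)."""
    return [
        StageWindow("Before flower bud opening", 92, 125),
        StageWindow("Flower bud opening", 126, 163),
        StageWindow("Flower open (Pollination period)", 164, 180),
        StageWindow("Fruit maturation", 181, 220),
        StageWindow("After fruit maturation (Harvest)", 221, 244),
    ]


def season_window() -> StageWindow:
    """The whole growing season, April 1 to August 31 (days 91-243)."""
    return StageWindow("Season (April-August)", 91, 243)


def _prepare(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"daily weather records lack columns {missing}")
    df = records.copy()
    df["date"] = pd.to_datetime(df["date"])
    df = df.drop_duplicates(subset="date").sort_values("date")
    df["doy"] = df["date"].dt.dayofyear
    df["year"] = df["date"].dt.year
    return df


def _slice_window(df: pd.DataFrame, window: StageWindow) -> pd.DataFrame:
    return df[(df["doy"] >= window.start_day) & (df["doy"] <= window.end_day)]


def freezing_days(
    records: pd.DataFrame,
    window: StageWindow,
    threshold: float = FREEZING_THRESHOLD,
    use_tmin: bool = False,
) -> int:
    """Count days in the window with mean temperature strictly below -5 degC.

    ``use_tmin=True`` applies the criterion to the daily minimum instead of
    the daily mean.
    """
    df = _slice_window(_prepare(records), window)
    col = "tmin" if use_tmin else "tmean"
    temps = df[col].dropna()
    expected = window.end_day - window.start_day + 1
    if len(temps) < 0.8 * expected:
        logger.warning(
            "window %s: %d of %d days available; freezing count on available days",
            window.name,
            len(temps),
            expected,
        )
    return int((temps < threshold).sum())


def gdd(
    records: pd.DataFrame,
    base: float = GDD_BASE,
    start_day: int = GDD_START_DAY,
    end_day: int = 366,
) -> float:
    """Growing degree-days: sum of max(0, tmean - base) from ``start_day``."""
    if not np.isfinite(base):
        raise ValueError("base temperature must be finite")
    df = _prepare(records)
    df = df[(df["doy"] >= start_day) & (df["doy"] <= end_day)]
    exceedance = (df["tmean"].dropna() - base).clip(lower=0.0)
    return float(exceedance.sum())


def stage_features(
    records: pd.DataFrame,
    windows: list[StageWindow] | None = None,
    include_gdd: bool = False,
    freezing_for: set[str] | None = None,
    use_tmin: bool = False,
) -> pd.Series:
    """Per-window aggregates of one year of daily records.

    Returns a Series keyed ``<stage>_<index>`` with mean_temp (degC),
    total_precip (mm) and, where requested via ``freezing_for`` (None means
    every window), freezing_days; ``include_gdd`` adds cumulative
    degree-days from April 1 to each window's end.
    """
    if windows is None:
        windows = default_stage_windows()
    df = _prepare(records)
    out: dict[str, float] = {}
    for window in windows:
        sl = _slice_window(df, window)
        if sl.empty:
            raise ValueError(f"no records in window {window.name}")
        temps = sl["tmean"].dropna()
        precip = sl["precip"]
        if precip.isna().any():
            logger.warning(
                "window %s: %d missing precipitation days treated as 0",
                window.name,
                int(precip.isna().sum()),
            )
        out[f"{window.name}_mean_temp"] = float(temps.mean())
        out[f"{window.name}_total_precip"] = float(precip.fillna(0.0).sum())
        if freezing_for is None or window.name in freezing_for:
            out[f"{window.name}_freezing_days"] = float(
                (temps < FREEZING_THRESHOLD).sum()
                if not use_tmin
                else (sl["tmin"].dropna() < FREEZING_THRESHOLD).sum()
            )
        if include_gdd:
            out[f"{window.name}_gdd"] = gdd(df, end_day=window.end_day)
    return pd.Series(out)


def historical_features(
    records: pd.DataFrame,
    target_year: int,
    windows: list[StageWindow] | None = None,
    n_years: int = 6,
    **kwargs,
) -> pd.Series:
    """Average stage features over the ``n_years`` years preceding
    ``target_year`` (default six years, i.e. three crop cycles)."""
    df = _prepare(records)
    wanted = list(range(target_year - n_years, target_year))
    missing = sorted(set(wanted) - set(df["year"].unique()))
    if missing:
        raise ValueError(
            f"historical features for {target_year} need years {wanted}; "
            f"missing {missing}"
        )
    per_year = [
        stage_features(df[df["year"] == y], windows, **kwargs) for y in wanted
    ]
    return pd.concat(per_year, axis=1).mean(axis=1)
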