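"""Assemble model design matrices from observation tables and daily weather.

An observation row carries N-P-K doses (kg/ha), leaf concentrations of
N, P, K, Ca, Mg (g/kg) and B, Al (mg/kg), soil Mehlich-3 P, K, Ca, Mg
(mg/kg), soil pH and berry yield (kg/ha). Here those raw columns are turned
into the feature blocks the models consume: ilr balances for leaf and soil
compositions, plus seasonal, stage or 6-year-historical weather indices.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import weather as wx
from .compositions import (
    LEAF_KAPPA,
    SOIL_KAPPA,
    BalancePartition,
    ilr_array,
    leaf_partition,
    soil_partition,
)

__all__ = [
    "DOSE_COLUMNS",
    "LEAF_COLUMNS",
    "SOIL_COLUMNS",
    "leaf_parts_table",
    "soil_parts_table",
    "balance_features",
    "weather_feature_table",
    "assemble_features",
]

DOSE_COLUMNS = ["dose_N", "dose_P", "dose_K"]
#: leaf N, P, K, Ca, Mg reported in g/kg; trace elements B, Al in mg/kg
LEAF_COLUMNS = {
    "leaf_N": 1.0,
    "leaf_P": 1.0,
    "leaf_K": 1.0,
    "leaf_Ca": 1.0,
    "leaf_Mg": 1.0,
    "leaf_B": 1e-3,
    "leaf_Al": 1e-3,
}
SOIL_COLUMNS = ["soil_P", "soil_K", "soil_Ca", "soil_Mg"]


def leaf_parts_table(obs: pd.DataFrame) -> np.ndarray:
    """(n, 8) leaf parts in g/kg incl. filling value, closed to 1000."""
    raw = np.column_stack(
        [obs[c].to_numpy(dtype=float) * f for c, f in LEAF_COLUMNS.items()]
    )
    fv = LEAF_KAPPA - raw.sum(axis=1)
    if (fv <= 0).any():
        bad = obs.index[fv <= 0].tolist()
        raise ValueError(f"no room for leaf filling value in rows {bad}")
    return np.column_stack([raw, fv])


def soil_parts_table(obs: pd.DataFrame) -> np.ndarray:
    """(n, 5) soil parts in mg/kg incl. filling value, closed to 1e6."""
    raw = obs[SOIL_COLUMNS].to_numpy(dtype=float)
    fv = SOIL_KAPPA - raw.sum(axis=1)
    if (fv <= 0).any():
        bad = obs.index[fv <= 0].tolist()
        raise ValueError(f"no room for soil filling value in rows {bad}")
    return np.column_stack([raw, fv])


def balance_features(obs: pd.DataFrame) -> pd.DataFrame:
    """Leaf and soil ilr balances, columns named ``leaf [den | num]`` etc."""
    leaf, soil = leaf_partition(), soil_partition()
    leaf_b = ilr_array(leaf_parts_table(obs), leaf)
    soil_b = ilr_array(soil_parts_table(obs), soil)
    cols = [f"leaf {n}" for n in leaf.balance_names()] + [
        f"soil {n}" for n in soil.balance_names()
    ]
    return pd.DataFrame(
        np.column_stack([leaf_b, soil_b]), columns=cols, index=obs.index
    )


def _site_year_features(
    weather_df: pd.DataFrame,
    site_years: pd.DataFrame,
    kind: str,
    windows,
    **kwargs,
) -> pd.DataFrame:
    rows = {}
    for site, year in site_years.itertuples(index=False):
        records = weather_df[weather_df["site"] == site]
        if kind == "historical":
            feats = wx.historical_features(records, year, windows, **kwargs)
        elif kind == "stage":
            feats = wx.stage_features(
                records[pd.to_datetime(records["date"]).dt.year == year],
                windows,
                **kwargs,
            )
        else:
            raise ValueError(f"unknown weather feature kind {kind!r}")
        rows[(site, year)] = feats
    return pd.DataFrame(rows).T


def weather_feature_table(
    obs: pd.DataFrame,
    weather_df: pd.DataFrame,
    kind: str = "historical",
    windows=None,
    prefix: str = "hist ",
    **kwargs,
) -> pd.DataFrame:
    """Per-observation weather features, computed once per (site, year).

    ``kind='historical'`` averages stage indices over the six preceding
    years (the predictive model's view); ``kind='stage'`` uses the
    observation year itself (the investigative view).
    """
    site_years = obs[["site", "year"]].drop_duplicates()
    table = _site_year_features(weather_df, site_years, kind, windows, **kwargs)
    table.columns = [f"{prefix}{c}" for c in table.columns]
    keys = pd.MultiIndex.from_frame(obs[["site", "year"]])
    out = table.loc[keys]
    out.index = obs.index
    return out


def assemble_features(
    obs: pd.DataFrame,
    weather_df: pd.DataFrame,
    kind: str = "historical",
    include_freezing: bool = False,
) -> pd.DataFrame:
    """The predictive feature matrix: doses, balances, pH, weather.

    Freezing-day indices are excluded from the historical (predictive)
    feature set by default: their 6-year averages are too erratic from year
    to year to carry predictive signal.
    """
    freezing_for = None if include_freezing else set()
    weather_feats = weather_feature_table(
        obs, weather_df, kind=kind, freezing_for=freezing_for
    )
    return pd.concat(
        [
            obs[DOSE_COLUMNS],
            balance_features(obs),
            obs[["pH"]],
            weather_feats,
        ],
        axis=1,
    )
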