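"""End-to-end pipeline: simulate -> features -> investigate -> fit ->
evaluate -> optimize, with every artifact written to disk and a manifest
capturing seeds and configuration for reproducibility."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .features import assemble_features
from .investigative import model_2year, model_bearing_year
from .optimizer import OptimizerConfig, portrait
from .surrogate import (
    YieldSurrogate,
    classification_report_at_cutoff,
    regression_metrics,
    split,
)
from .synthetic import SyntheticConfig, generate_dataset

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)


def _stage(name: str, **info) -> None:
    logger.info("stage=%s %s", name, " ".join(f"{k}={v}" for k, v in info.items()))


def run_pipeline(
    out_dir: str | Path,
    seed: int = 0,
    n_obs: int = 300,
    train_fraction: float = 0.7,
    cutoff: float = 5000.0,
    portrait_rows: int | None = 25,
    optimizer_config: OptimizerConfig | None = None,
    synthetic_config: SyntheticConfig | None = None,
) -> dict:
    """Run the full synthetic pipeline; returns the manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    config = synthetic_config or SyntheticConfig(n_obs=n_obs)
    obs, weather_df, gt = generate_dataset(config, seed=seed)
    obs.to_csv(out / "observations.csv", index=False)
    weather_df.to_csv(out / "weather_daily.csv", index=False)
    (out / "ground_truth.json").write_text(json.dumps(gt.to_dict(), indent=2))
    _stage("simulate", rows=len(obs))

    features = assemble_features(obs, weather_df)
    features.to_csv(out / "features.csv", index=False)
    _stage("features", columns=features.shape[1])

    for name, fitter in (
        ("model_2year", model_2year),
        ("model_bearing_year", model_bearing_year),
    ):
        model = fitter(obs, weather_df, random_state=seed)
        model.summary().to_csv(out / f"{name}_posterior.csv", index=False)
    _stage("investigate", models=2)

    spec = split(len(obs), train_fraction, seed=seed)
    y = obs["yield"].to_numpy(dtype=float)
    surrogate = YieldSurrogate(random_state=seed).fit(
        features.iloc[spec.train_idx], y[spec.train_idx]
    )
    (out / "surrogate.json").write_text(surrogate.to_json())
    _stage("fit", train=len(spec.train_idx), test=len(spec.test_idx))

    pred_train = surrogate.predict(features.iloc[spec.train_idx])
    pred_test = surrogate.predict(features.iloc[spec.test_idx])
    report = classification_report_at_cutoff(pred_test, y[spec.test_idx], cutoff)
    evaluation = {
        "train": regression_metrics(pred_train, y[spec.train_idx]),
        "test": regression_metrics(pred_test, y[spec.test_idx]),
        "classification": {
            "cutoff": cutoff,
            "accuracy": report.accuracy,
            "positive_predictive_rate": report.positive_predictive_rate,
            "negative_predictive_rate": report.negative_predictive_rate,
            "confusion": {
                "tp": report.tp,
                "fp": report.fp,
                "tn": report.tn,
                "fn": report.fn,
            },
        },
    }
    (out / "evaluation.json").write_text(json.dumps(evaluation, indent=2))
    _stage("evaluate", test_rmse=round(evaluation["test"]["rmse"], 1))

    opt_config = optimizer_config or OptimizerConfig(seed=seed)
    portrait_df = portrait(
        features, surrogate, opt_config, max_rows=portrait_rows, seed=seed
    )
    portrait_df.to_csv(out / "portrait.csv")
    _stage("portrait", rows=len(portrait_df))

    manifest = {
        "version": __version__,
        "seed": seed,
        "n_obs": len(obs),
        "train_fraction": train_fraction,
        "cutoff": cutoff,
        "portrait_rows": portrait_rows,
        "observations_sha256": hashlib.sha256(
            (out / "observations.csv").read_bytes()
        ).hexdigest(),
        "evaluation": evaluation,
        "portrait_medians": {
            "gain": float(portrait_df["gain"].median()),
            "yield_factor": float(portrait_df["yield_factor"].median()),
            "leaf_aitchison_distance": float(
                portrait_df["leaf_aitchison_distance"].median()
            ),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
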