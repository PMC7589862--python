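"""Markov-chain random-walk optimization of controllable crop features.

Starting from an observed state, the walk repeatedly proposes random
candidates within an adaptive radius over the FREE features (leaf balances,
soil balances, pH, N-P-K doses) while the fixed features (historical
weather) stay bit-identical; candidates that extrapolate beyond the
training envelope — Mahalanobis distance above a critical value, or any
free feature outside the training min/max — are discarded; the best
surviving candidate is accepted if it improves the predicted yield, in
which case the radius shrinks, otherwise the state is kept and the radius
grows. Accepted predicted yields are therefore non-decreasing, and every
accepted state (past the start) lies inside the applicability domain.

The walk runs in the surrogate's standardized feature space; leaf and soil
balance blocks are back-transformed to concentrations only for reporting,
which guarantees every reported composition is positive and closed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .compositions import (
    LEAF_KAPPA,
    SOIL_KAPPA,
    Composition,
    aitchison_distance,
    close,
    ilr_inverse,
    leaf_partition,
    perturbation_ratio,
    soil_partition,
)
from .features import DOSE_COLUMNS
from .surrogate import TrainingEnvelope, YieldSurrogate

__all__ = [
    "OptimizerConfig",
    "WalkState",
    "OptimizationTrace",
    "Recommendation",
    "propose",
    "envelope_filter",
    "step",
    "random_walk",
    "optimize_observation",
    "portrait",
    "controllable_features",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OptimizerConfig:
    """Tuning knobs of the random walk (standardized-space units)."""

    n_candidates: int = 60
    initial_radius: float = 1.0
    shrink: float = 0.95
    growth: float = 1.03
    max_iter: int = 500
    critical_quantile: float = 0.975
    critical_distance: float | None = None  # overrides the chi-square rule
    radius_floor: float = 1e-4
    radius_cap_factor: float = 10.0
    floor_patience: int = 20
    proposal: str = "ball"  # or "gauss"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.shrink < 1.0 < self.growth:
            raise ValueError("need 0 < shrink < 1 < growth")
        if self.n_candidates < 1:
            raise ValueError("n_candidates must be >= 1")
        if self.initial_radius <= 0:
            raise ValueError("initial radius must be positive")
        if self.critical_distance is not None and self.critical_distance <= 0:
            raise ValueError("critical distance must be positive")


@dataclass(frozen=True)
class WalkState:
    """One accepted point of the walk."""

    iteration: int
    vector: np.ndarray  # standardized feature vector
    predicted_yield: float
    radius: float


@dataclass
class OptimizationTrace:
    """Accepted states plus per-iteration proposal diagnostics."""

    states: list[WalkState] = field(default_factory=list)
    n_proposed: list[int] = field(default_factory=list)
    n_survived: list[int] = field(default_factory=list)
    accepted: list[bool] = field(default_factory=list)

    @property
    def yields(self) -> np.ndarray:
        return np.array([s.predicted_yield for s in self.states])

    @property
    def final(self) -> WalkState:
        return self.states[-1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": [s.iteration for s in self.states],
                "radius": [s.radius for s in self.states],
                "predicted_yield": self.yields,
            }
        )


@dataclass
class Recommendation:
    """Locally optimal controllable state with Aitchison diagnostics."""

    leaf_composition: Composition
    soil_composition: Composition
    ph: float
    doses: dict[str, float]
    predicted_yield_initial: float
    predicted_yield_optimal: float
    leaf_distance: float
    soil_distance: float
    leaf_ratios: dict[str, float]
    soil_ratios: dict[str, float]

    @property
    def gain(self) -> float:
        return self.predicted_yield_optimal - self.predicted_yield_initial

    @property
    def yield_factor(self) -> float:
        return self.predicted_yield_optimal / self.predicted_yield_initial

    def to_dict(self) -> dict:
        return {
            "leaf_composition": dict(
                zip(self.leaf_composition.labels, self.leaf_composition.values.tolist())
            ),
            "soil_composition": dict(
                zip(self.soil_composition.labels, self.soil_composition.values.tolist())
            ),
            "pH": self.ph,
            "doses": self.doses,
            "predicted_yield_initial": self.predicted_yield_initial,
            "predicted_yield_optimal": self.predicted_yield_optimal,
            "gain": self.gain,
            "yield_factor": self.yield_factor,
            "leaf_aitchison_distance": self.leaf_distance,
            "soil_aitchison_distance": self.soil_distance,
            "leaf_ratios": self.leaf_ratios,
            "soil_ratios": self.soil_ratios,
        }


def propose(
    vector: np.ndarray,
    radius: float,
    free_idx: np.ndarray,
    n_candidates: int,
    rng: np.random.Generator,
    proposal: str = "ball",
) -> np.ndarray:
    """``n_candidates`` points around ``vector`` moving only free features.

    ``ball``: uniform in the Euclidean ball of ``radius`` over the free
    coordinates; ``gauss``: isotropic Gaussian with sd ``radius``.
    """
    free_idx = np.asarray(free_idx)
    if free_idx.size == 0:
        raise ValueError("empty free-feature mask")
    if radius <= 0:
        raise ValueError("radius must be positive")
    k = free_idx.size
    direction = rng.standard_normal((n_candidates, k))
    if proposal == "ball":
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        lengths = radius * rng.random(n_candidates) ** (1.0 / k)
        offsets = direction * lengths[:, None]
    elif proposal == "gauss":
        offsets = radius * direction
    else:
        raise ValueError(f"unknown proposal {proposal!r}")
    candidates = np.tile(np.asarray(vector, dtype=float), (n_candidates, 1))
    candidates[:, free_idx] += offsets
    return candidates


def envelope_filter(
    candidates: np.ndarray,
    envelope: TrainingEnvelope,
    critical_distance: float,
    free_idx=None,
) -> np.ndarray:
    """Boolean survival mask: inside the Mahalanobis ellipsoid AND inside
    the training min/max box on the free features."""
    dist_ok = envelope.mahalanobis(candidates) <= critical_distance
    return dist_ok & envelope.within_bounds(candidates, free_idx)


def step(
    state: WalkState,
    predict_fn,
    envelope: TrainingEnvelope,
    config: OptimizerConfig,
    rng: np.random.Generator,
    free_idx: np.ndarray,
    critical_distance: float,
    radius_cap: float,
) -> tuple[WalkState, int, bool]:
    """One walk iteration: propose, filter, evaluate, accept or grow.

    Ties among equally best survivors break to the lowest candidate index
    (the seeded proposal order). Returns (next state, survivors, accepted).
    """
    candidates = propose(
        state.vector, state.radius, free_idx, config.n_candidates, rng, config.proposal
    )
    mask = envelope_filter(candidates, envelope, critical_distance, free_idx)
    survivors = candidates[mask]
    if survivors.shape[0] > 0:
        yields = np.asarray(predict_fn(survivors), dtype=float)
        best = int(np.argmax(yields))  # argmax takes the first maximum
        if yields[best] > state.predicted_yield:
            next_state = WalkState(
                state.iteration + 1,
                survivors[best],
                float(yields[best]),
                max(state.radius * config.shrink, config.radius_floor),
            )
            return next_state, int(mask.sum()), True
    next_state = replace(
        state,
        iteration=state.iteration + 1,
        radius=min(state.radius * config.growth, radius_cap),
    )
    return next_state, int(mask.sum()), False


def random_walk(
    start: np.ndarray,
    predict_fn,
    envelope: TrainingEnvelope,
    config: OptimizerConfig,
    free_idx=None,
) -> OptimizationTrace:
    """Run the walk from ``start`` until max_iter or a collapsed radius.

    ``predict_fn`` maps an (m, p) array of standardized states to predicted
    yields. The start state is exempt from the envelope check (an observed
    point may sit outside it); every accepted state thereafter is inside.
    """
    start = np.asarray(start, dtype=float)
    free_idx = (
        np.arange(start.size) if free_idx is None else np.asarray(free_idx)
    )
    rng = np.random.default_rng(config.seed)
    critical = (
        config.critical_distance
        if config.critical_distance is not None
        else envelope.critical_distance(config.critical_quantile)
    )
    if envelope.mahalanobis(start)[0] > critical:
        logger.warning(
            "start state is outside the training envelope "
            "(Mahalanobis %.2f > %.2f); walking anyway",
            envelope.mahalanobis(start)[0],
            critical,
        )
    radius_cap = config.radius_cap_factor * config.initial_radius
    state = WalkState(
        0, start, float(np.asarray(predict_fn(start[None, :]))[0]), config.initial_radius
    )
    trace = OptimizationTrace(states=[state])
    at_floor = 0
    for _ in range(config.max_iter):
        state, n_surv, accepted = step(
            state, predict_fn, envelope, config, rng, free_idx, critical, radius_cap
        )
        trace.n_proposed.append(config.n_candidates)
        trace.n_survived.append(n_surv)
        trace.accepted.append(accepted)
        if accepted:
            trace.states.append(state)
        stalled = state.radius <= config.radius_floor and not accepted
        at_floor = at_floor + 1 if stalled else 0
        if at_floor >= config.floor_patience:
            break
    return trace


def controllable_features(feature_names: list[str]) -> list[str]:
    """The features the grower can act on: doses, balances, pH."""
    return [
        c
        for c in feature_names
        if c in DOSE_COLUMNS or c == "pH" or c.startswith(("leaf ", "soil "))
    ]


def _compositions_from_row(row: pd.Series) -> tuple[Composition, Composition]:
    leaf, soil = leaf_partition(), soil_partition()
    leaf_b = row[[f"leaf {n}" for n in leaf.balance_names()]].to_numpy(dtype=float)
    soil_b = row[[f"soil {n}" for n in soil.balance_names()]].to_numpy(dtype=float)
    return (
        ilr_inverse(leaf_b, leaf, LEAF_KAPPA),
        ilr_inverse(soil_b, soil, SOIL_KAPPA),
    )


def optimize_observation(
    features_row: pd.Series,
    model: YieldSurrogate,
    config: OptimizerConfig | None = None,
) -> tuple[OptimizationTrace, Recommendation]:
    """Walk one observation's controllables to a local yield optimum.

    Weather features stay fixed at the observation's historical values
    (conditioning); the Recommendation reports back-transformed leaf and
    soil compositions, pH, doses, the predicted yield gain, Aitchison
    distances from the observed compositions and per-part observed/target
    perturbation ratios.
    """
    config = config or OptimizerConfig()
    names = model.feature_names_in_
    free = controllable_features(names)
    free_idx = np.array([names.index(c) for c in free])
    start = model.transform(features_row.to_frame().T)[0]
    trace = random_walk(
        start, model.predict_standardized, model.envelope_, config, free_idx
    )
    final_row = model.inverse_transform(trace.final.vector).iloc[0]
    observed_row = model.inverse_transform(start).iloc[0]
    leaf_opt, soil_opt = _compositions_from_row(final_row)
    leaf_obs, soil_obs = _compositions_from_row(observed_row)
    rec = Recommendation(
        leaf_composition=leaf_opt,
        soil_composition=soil_opt,
        ph=float(final_row["pH"]),
        doses={nut: float(final_row[f"dose_{nut}"]) for nut in ("N", "P", "K")},
        predicted_yield_initial=trace.states[0].predicted_yield,
        predicted_yield_optimal=trace.final.predicted_yield,
        leaf_distance=aitchison_distance(leaf_obs, leaf_opt),
        soil_distance=aitchison_distance(soil_obs, soil_opt),
        leaf_ratios=perturbation_ratio(leaf_obs, leaf_opt),
        soil_ratios=perturbation_ratio(soil_obs, soil_opt),
    )
    return trace, rec


def portrait(
    features: pd.DataFrame,
    model: YieldSurrogate,
    config: OptimizerConfig | None = None,
    max_rows: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-observation optimization portrait.

    Runs :func:`optimize_observation` on every row (or a seeded subsample of
    ``max_rows``) and returns one row per observation: optimal leaf
    concentrations, Aitchison distances, predicted gains and yield factors.
    Per-row failures are logged and skipped.
    """
    config = config or OptimizerConfig()
    rows = features
    if max_rows is not None and len(features) > max_rows:
        keep = np.random.default_rng(seed).choice(
            len(features), size=max_rows, replace=False
        )
        rows = features.iloc[np.sort(keep)]
    records = []
    n_failed = 0
    for i, (idx, row) in enumerate(rows.iterrows()):
        try:
            _, rec = optimize_observation(
                row, model, replace(config, seed=config.seed + i)
            )
        except Exception:  # propagate nothing: a portrait is an aggregate
            logger.exception("optimization failed for row %s; skipped", idx)
            n_failed += 1
            continue
        record = {
            "observation": idx,
            "predicted_yield_initial": rec.predicted_yield_initial,
            "predicted_yield_optimal": rec.predicted_yield_optimal,
            "gain": rec.gain,
            "yield_factor": rec.yield_factor,
            "leaf_aitchison_distance": rec.leaf_distance,
            "soil_aitchison_distance": rec.soil_distance,
            "pH_opt": rec.ph,
        }
        for nut, dose in rec.doses.items():
            record[f"dose_{nut}_opt"] = dose
        for lab, val in zip(
            rec.leaf_composition.labels, rec.leaf_composition.values
        ):
            record[f"leaf_{lab}_opt"] = val
        records.append(record)
    if n_failed:
        logger.warning("portrait: %d of %d optimizations failed", n_failed, len(rows))
    return pd.DataFrame.from_records(records).set_index("observation")
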