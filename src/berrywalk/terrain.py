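"""Two-dimensional terrain demo of the random-walk optimizer.

A synthetic volcano-like height grid (87 x 61 cells, a broad main peak and
two smaller bumps; entirely generated here, no external terrain data)
stands in for the yield surface: walking XY coordinates toward higher
topography is a visual metaphor for walking nutrient balances toward
higher yield. The walk starts at (42, 8) with a radius of 3 grid units.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .optimizer import OptimizerConfig, OptimizationTrace, random_walk
from .surrogate import TrainingEnvelope

__all__ = ["bumpy_grid", "climb_terrain", "grid_height_tolerance"]

GRID_SHAPE = (87, 61)
DEFAULT_START = (42.0, 8.0)
DEFAULT_RADIUS = 3.0


def bumpy_grid(shape: tuple[int, int] = GRID_SHAPE) -> np.ndarray:
    """Synthetic bumpy height grid (meters): one dominant peak, two bumps."""
    x = np.arange(shape[0], dtype=float)
    y = np.arange(shape[1], dtype=float)
    X, Y = np.meshgrid(x, y, indexing="ij")
    z = (
        94.0
        + 80.0 * np.exp(-((X - 30.0) ** 2 + (Y - 35.0) ** 2) / 350.0)
        + 35.0 * np.exp(-((X - 62.0) ** 2 + (Y - 15.0) ** 2) / 220.0)
        + 25.0 * np.exp(-((X - 12.0) ** 2 + (Y - 10.0) ** 2) / 150.0)
    )
    return z


def grid_height_tolerance(z: np.ndarray) -> float:
    """One grid-cell height: the largest adjacent-cell height difference."""
    return float(
        max(np.abs(np.diff(z, axis=0)).max(), np.abs(np.diff(z, axis=1)).max())
    )


def _grid_envelope(z: np.ndarray) -> TrainingEnvelope:
    nx, ny = z.shape
    X, Y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    points = np.column_stack([X.ravel(), Y.ravel()]).astype(float)
    return TrainingEnvelope.from_rows(points)


def climb_terrain(
    z: np.ndarray | None = None,
    start: tuple[float, float] = DEFAULT_START,
    radius: float = DEFAULT_RADIUS,
    seed: int = 0,
    max_iter: int = 500,
    n_candidates: int = 60,
) -> OptimizationTrace:
    """Run the random walk uphill on the height grid; returns the trace."""
    z = bumpy_grid() if z is None else z
    interp = RegularGridInterpolator(
        (np.arange(z.shape[0], dtype=float), np.arange(z.shape[1], dtype=float)),
        z,
        bounds_error=False,
        fill_value=float(z.min()),
    )
    config = OptimizerConfig(
        n_candidates=n_candidates,
        initial_radius=radius,
        max_iter=max_iter,
        seed=seed,
    )
    return random_walk(
        np.asarray(start, dtype=float),
        lambda pts: interp(pts),
        _grid_envelope(z),
        config,
    )
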