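"""Grid simulations of predicted abundance over the covariate space.

A trained model is evaluated over a rectangular grid spanning the range
of the training (seasonal) data — temperature -1.8 to 2.8 degC, day
length 0-24 h, Chl-a 0.01-0.61 ug/L, with viral models sliced at 5, 50,
100, 150 and 200 m depth.  Predictions are inverse-scaled to natural
abundance units and deliberately NOT clipped at zero: negative predicted
abundance marks covariate regions the model extrapolates into.  A
companion histogram of the data over the same axes shows where the grid
is actually supported by observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_search import CandidateResult, predict_abundance
from .data_prep import Scaler

__all__ = [
    "Axis",
    "SimulationGrid",
    "simulate_grid",
    "total_grid",
    "support_histogram",
    "SEASONAL_RANGES",
    "VIRAL_SIM_DEPTHS",
]

#: Seasonal-data covariate ranges used for simulation axes.
SEASONAL_RANGES = {
    "temperature_c": (-1.8, 2.8),
    "day_length_h": (0.0, 24.0),
    "chl_a_ug_l": (0.01, 0.61),
    "depth_m": (1.0, 225.0),
}

#: Depth slices (m) at which the viral models are simulated.
VIRAL_SIM_DEPTHS = (5.0, 50.0, 100.0, 150.0, 200.0)


@dataclass
class Axis:
    name: str
    values: np.ndarray

    @classmethod
    def linspace(cls, name: str, lo: float, hi: float, n: int = 50) -> "Axis":
        return cls(name, np.linspace(lo, hi, n))

    @classmethod
    def fixed(cls, name: str, levels) -> "Axis":
        return cls(name, np.asarray(levels, dtype=float))


@dataclass
class SimulationGrid:
    axes: list  # list[Axis], slow-to-fast
    values: np.ndarray  # shape = tuple(len(a.values) for a in axes)
    model_id: str
    extrapolation: np.ndarray | None = None  # same shape, True = outside range

    def to_frame(self) -> pd.DataFrame:
        mesh = np.meshgrid(*[a.values for a in self.axes], indexing="ij")
        data = {a.name: m.ravel() for a, m in zip(self.axes, mesh)}
        data["prediction"] = self.values.ravel()
        if self.extrapolation is not None:
            data["extrapolated"] = self.extrapolation.ravel()
        return pd.DataFrame(data)


def simulate_grid(
    result: CandidateResult,
    axes: list,
    scaler: Scaler,
    fixed: dict | None = None,
) -> SimulationGrid:
    """Evaluate a trained model on a covariate grid.

    ``axes`` plus ``fixed`` must together cover the model's input subset
    exactly.  Axis values outside the seasonal data range are flagged in
    the extrapolation mask (and a warning raised) but still evaluated.
    """
    fixed = fixed or {}
    names = [a.name for a in axes]
    inputs = set(result.spec.inputs)
    covered = set(names) | set(fixed)
    if covered != inputs:
        raise ValueError(
            f"axes+fixed {sorted(covered)} do not match model inputs {sorted(inputs)}"
        )
    out_of_range = np.zeros([len(a.values) for a in axes], dtype=bool)
    for dim, a in enumerate(axes):
        lo, hi = SEASONAL_RANGES.get(a.name, (-np.inf, np.inf))
        bad = (a.values < lo) | (a.values > hi)
        if bad.any():
            import warnings

            warnings.warn(
                f"axis {a.name!r} extends outside the seasonal data range",
                stacklevel=2,
            )
            shape = [1] * len(axes)
            shape[dim] = len(a.values)
            out_of_range |= bad.reshape(shape)
    mesh = np.meshgrid(*[a.values for a in axes], indexing="ij")
    table = pd.DataFrame({n: m.ravel() for n, m in zip(names, mesh)})
    for k, v in fixed.items():
        table[k] = v
    pred = predict_abundance(result, table, scaler)
    return SimulationGrid(
        axes=list(axes),
        values=pred.reshape(out_of_range.shape),
        model_id=result.spec.spec_id,
        extrapolation=out_of_range,
    )


def total_grid(grid_a: SimulationGrid, grid_b: SimulationGrid) -> SimulationGrid:
    """Node-wise sum of two grids over identical axes (component models
    of total prokaryote or total virus abundance)."""
    if len(grid_a.axes) != len(grid_b.axes) or any(
        a.name != b.name or not np.array_equal(a.values, b.values)
        for a, b in zip(grid_a.axes, grid_b.axes)
    ):
        raise ValueError("grids have different axes")
    extrap = None
    if grid_a.extrapolation is not None and grid_b.extrapolation is not None:
        extrap = grid_a.extrapolation | grid_b.extrapolation
    return SimulationGrid(
        axes=grid_a.axes,
        values=grid_a.values + grid_b.values,
        model_id=f"{grid_a.model_id}+{grid_b.model_id}",
        extrapolation=extrap,
    )


def support_histogram(table: pd.DataFrame, axes: list) -> tuple[np.ndarray, list]:
    """Histogram of the data over grid axes; counts sum to the row count.

    For each axis the bin edges are the midpoints between consecutive
    grid values, extended to +-inf at the ends, so every sample lands in
    exactly one bin.  Returns (counts, edges_per_axis).
    """
    edges = []
    for a in axes:
        v = np.asarray(a.values, dtype=float)
        if v.size == 1:
            e = np.array([-np.inf, np.inf])
        else:
            mid = (v[:-1] + v[1:]) / 2.0
            e = np.concatenate([[-np.inf], mid, [np.inf]])
        edges.append(e)
    sample = np.column_stack(
        [table[a.name].to_numpy(dtype=float) for a in axes]
    ) if len(table) else np.empty((0, len(axes)))
    counts, _ = np.histogramdd(sample, bins=edges)
    return counts.astype(int), edges
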