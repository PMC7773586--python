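"""Clock alignment and aggregation of single-cell kinetic traces.

Every cell carries its own clock zero ``t0`` — the frame of mitotic spindle
breakage — and all comparisons between cells and strains are made after
re-timing each trace to that clock.  Aligned traces are linearly interpolated
onto a common 1-min grid (default −45…+45 min) and aggregated to per-gridpoint
mean ± SD ("mean kinetics").  Gridpoints observed in fewer than ``n_min``
cells are masked (NaN).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .panel import DEFAULT_GRID

__all__ = [
    "KineticTrace",
    "MeanKinetics",
    "align_trace",
    "aggregate",
    "normalize",
    "traces_to_frame",
    "traces_from_frame",
    "read_traces_csv",
    "write_traces_csv",
    "read_mean_kinetics_csv",
    "write_mean_kinetics_csv",
]


@dataclass
class KineticTrace:
    """One cell × one channel time series, in raw (unaligned) time."""

    cell_id: str
    protein_id: str
    times: np.ndarray  # raw timestamps, min
    intensity: np.ndarray  # background-subtracted, a.u.
    t0: float  # clock zero (spindle breakage), raw min
    condition: str = "control"
    diameter: np.ndarray | None = None  # μm, optional

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.diameter is not None:
            self.diameter = np.asarray(self.diameter, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValueError("trace needs at least two timepoints")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.intensity.shape != self.times.shape:
            raise ValueError("times and intensity must have equal length")
        if self.t0 is not None and not (self.times[0] <= self.t0 <= self.times[-1]):
            raise ValueError("t0 outside the observed time range")


@dataclass
class MeanKinetics:
    """Per-gridpoint mean ± SD of aligned traces; masked points are NaN."""

    protein_id: str
    grid: np.ndarray  # min, uniform
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray  # cells contributing per gridpoint
    condition: str = "control"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        steps = np.diff(self.grid)
        if self.grid.size < 2 or not np.allclose(steps, steps[0]):
            raise ValueError("grid must be uniform")
        for name in ("mean", "sd", "n"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.grid.shape:
                raise ValueError(f"{name} must match grid length")
            setattr(self, name, arr)
        if np.any(self.sd[np.isfinite(self.sd)] < 0):
            raise ValueError("sd must be non-negative")

    @property
    def unmasked(self) -> np.ndarray:
        return np.isfinite(self.mean)


def align_trace(trace: KineticTrace, grid: np.ndarray | None = None,
                values: np.ndarray | None = None) -> np.ndarray:
    """Re-time a trace to its spindle-breakage clock and resample to ``grid``.

    Returns the trace linearly interpolated onto the grid, with NaN at
    gridpoints outside the observed interval (no extrapolation).  ``values``
    defaults to the intensity channel; pass ``trace.diameter`` to align the
    ring-diameter channel instead.
    """
    if trace.t0 is None or not np.isfinite(trace.t0):
        raise ValueError(f"cell {trace.cell_id}: clock zero t0 is missing")
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    y = trace.intensity if values is None else np.asarray(values, dtype=float)
    t = trace.times - trace.t0
    out = np.interp(grid, t, y, left=np.nan, right=np.nan)
    out[(grid < t[0]) | (grid > t[-1])] = np.nan
    return out


def aggregate(aligned: Iterable[np.ndarray] | Sequence[KineticTrace],
              n_min: int = 10, grid: np.ndarray | None = None,
              protein_id: str = "", condition: str = "control") -> MeanKinetics:
    """Per-gridpoint sample mean and SD (ddof=1) over non-missing cells."""
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    rows = [align_trace(a, grid) if isinstance(a, KineticTrace) else np.asarray(a, float)
            for a in aligned]
    if not rows:
        raise ValueError("aggregate: no traces given")
    stack = np.vstack(rows)
    if stack.shape[1] != grid.size:
        raise ValueError("aligned traces do not match the grid")
    ok = np.isfinite(stack)
    n = ok.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, np.nansum(np.where(ok, stack, 0.0), axis=0) / np.maximum(n, 1), np.nan)
        dev = np.where(ok, stack - mean, 0.0)
        var = np.where(n > 1, (dev ** 2).sum(axis=0) / np.maximum(n - 1, 1), np.nan)
    sd = np.sqrt(var)
    masked = n < n_min
    mean = np.where(masked, np.nan, mean)
    sd = np.where(masked, np.nan, sd)
    return MeanKinetics(protein_id=protein_id, grid=grid, mean=mean, sd=sd,
                        n=n, condition=condition)


def normalize(mk: MeanKinetics, mode: str = "none") -> MeanKinetics:
    """Rescale a mean curve: ``max1`` divides by the peak mean;
    ``baseline0_max1`` first subtracts the baseline (mean of the first five
    unmasked gridpoints).  SD is scaled by the same factor."""
    if mode not in ("none", "max1", "baseline0_max1"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    if mode == "none":
        return MeanKinetics(mk.protein_id, mk.grid.copy(), mk.mean.copy(),
                            mk.sd.copy(), mk.n.copy(), mk.condition)
    mean = mk.mean.copy()
    idx = np.flatnonzero(mk.unmasked)
    if idx.size == 0:
        raise ValueError("normalize: curve fully masked")
    if mode == "baseline0_max1":
        mean = mean - np.nanmean(mean[idx[:5]])
    peak = np.nanmax(mean)
    if not peak > 0:
        raise ValueError("normalize: zero peak (flat or non-positive curve)")
    return MeanKinetics(mk.protein_id, mk.grid.copy(), mean / peak,
                        mk.sd / peak, mk.n.copy(), mk.condition)


# -- CSV I/O ------------------------------------------------------------------

_TRACE_COLS = ["cell_id", "protein", "condition", "time_min", "intensity_au",
               "diameter_um", "t0_min"]


def traces_to_frame(traces: Sequence[KineticTrace]) -> pd.DataFrame:
    rows = []
    for tr in traces:
        diam = tr.diameter if tr.diameter is not None else np.full(tr.times.shape, np.nan)
        rows.append(pd.DataFrame({
            "cell_id": tr.cell_id, "protein": tr.protein_id,
            "condition": tr.condition, "time_min": tr.times,
            "intensity_au": tr.intensity, "diameter_um": diam,
            "t0_min": tr.t0,
        }))
    return pd.concat(rows, ignore_index=True)[_TRACE_COLS]


def traces_from_frame(df: pd.DataFrame) -> list[KineticTrace]:
    out = []
    for (cell, prot, cond), g in df.groupby(["cell_id", "protein", "condition"], sort=False):
        g = g.sort_values("time_min")
        diam = g["diameter_um"].to_numpy()
        out.append(KineticTrace(
            cell_id=str(cell), protein_id=str(prot), condition=str(cond),
            times=g["time_min"].to_numpy(), intensity=g["intensity_au"].to_numpy(),
            t0=float(g["t0_min"].iloc[0]),
            diameter=None if np.all(np.isnan(diam)) else diam,
        ))
    return out


def write_traces_csv(traces: Sequence[KineticTrace], path: str | Path) -> None:
    traces_to_frame(traces).to_csv(path, index=False)


def read_traces_csv(path: str | Path | io.TextIOBase) -> list[KineticTrace]:
    return traces_from_frame(pd.read_csv(path))


def write_mean_kinetics_csv(mks: Sequence[MeanKinetics], path: str | Path) -> None:
    frames = [pd.DataFrame({
        "protein": mk.protein_id, "condition": mk.condition,
        "time_min": mk.grid, "mean_au": mk.mean, "sd_au": mk.sd, "n_cells": mk.n,
    }) for mk in mks]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_mean_kinetics_csv(path: str | Path) -> list[MeanKinetics]:
    df = pd.read_csv(path)
    out = []
    for (prot, cond), g in df.groupby(["protein", "condition"], sort=False):
        g = g.sort_values("time_min")
        out.append(MeanKinetics(
            protein_id=str(prot), condition=str(cond),
            grid=g["time_min"].to_numpy(), mean=g["mean_au"].to_numpy(),
            sd=g["sd_au"].to_numpy(), n=g["n_cells"].to_numpy()))
    return out
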