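"""Candidate regressors and confound matrix construction.

Six signal models are built from one paradigm/PetCO2 pair: two regressor
types (``PetCO2`` — the end-tidal CO2 course; ``Block`` — a boxcar over the
holds) crossed with three convolution models (``WoC`` no convolution,
``CSg`` single-gamma HRF, ``CDb`` double-gamma HRF).  Each candidate design
column is one (type, convolution, HRF delay, lag) combination: the high-res
source is shifted by the lag, sampled at the volume acquisition times and
min-max normalized to [0, 1].

Sign convention: a positive lag delays the regressor relative to the
stimulus, i.e. models a BOLD response arriving *later*.

Confounds are the 24 extended motion parameters (6 rigid-body, their
backward-difference derivatives, and the squares of both) plus one unit
spike column per motion-outlier volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .dataset import BoldDataset
from .hrf import HRFKernel
from .paradigm import BHParadigm

__all__ = [
    "GridSeries",
    "Regressor",
    "ConfoundMatrix",
    "MODEL_GRID",
    "build_block",
    "build_petco2",
    "convolve",
    "shift_and_sample",
    "extend_motion_params",
    "detect_motion_outliers",
    "build_confounds",
]

#: The six (regressor type, convolution) model families.
MODEL_GRID: tuple[tuple[str, str], ...] = tuple(
    (rt, conv) for rt in ("PetCO2", "Block") for conv in ("WoC", "CSg", "CDb")
)

DEFAULT_PAD = 24.0  # seconds; covers |bulk lag| (15) + lag sweep half-width (9)


@dataclass(frozen=True)
class GridSeries:
    """A series on a uniform time grid starting at ``t0`` with step ``dt``."""

    t0: float
    dt: float
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("values must be a 1-D series of length >= 2")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) * self.dt

    @property
    def t_end(self) -> float:
        return self.t0 + (self.values.size - 1) * self.dt

    def at(self, t: np.ndarray) -> np.ndarray:
        """Linear interpolation; edges are held at the boundary values."""
        return np.interp(np.asarray(t, dtype=float), self.times, self.values)


@dataclass(frozen=True)
class Regressor:
    """One candidate design column, with its provenance."""

    grid_dt: float
    values_highres: GridSeries
    values_tr: np.ndarray
    regressor_type: Literal["PetCO2", "Block"]
    convolution: Literal["WoC", "CSg", "CDb"]
    hrf_delay: float | None
    lag: float


@dataclass(frozen=True)
class ConfoundMatrix:
    columns: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        cols = np.asarray(self.columns, dtype=float)
        object.__setattr__(self, "columns", cols)
        if cols.ndim != 2 or cols.shape[1] != len(self.names):
            raise ValueError("columns/names mismatch")


def build_block(
    paradigm: BHParadigm, grid_dt: float = 0.1, pad: float = DEFAULT_PAD
) -> GridSeries:
    """Boxcar source: 1 during each hold, 0 elsewhere, on a padded grid."""
    if grid_dt <= 0:
        raise ValueError("grid_dt must be positive")
    t0 = -float(pad)
    n = int(round((paradigm.total_duration + 2 * pad) / grid_dt)) + 1
    t = t0 + np.arange(n) * grid_dt
    values = np.zeros(n)
    for start, end in paradigm.hold_intervals():
        values[(t >= start - 1e-9) & (t < end - 1e-9)] = 1.0
    return GridSeries(t0=t0, dt=float(grid_dt), values=values)


def build_petco2(
    trace,
    grid_dt: float = 0.1,
    *,
    total_duration: float,
    pad: float = DEFAULT_PAD,
    warmup: float = 40.0,
) -> GridSeries:
    """Resample an end-tidal CO2 trace onto the padded scan grid.

    ``trace`` is any object with ``times`` and ``values`` attributes (a
    ``PetCO2Trace``).  Samples outside the trace's coverage are held at the
    nearest value.  A trace covering less than half the scan is rejected.

    The grid extends ``pad + warmup`` s before the scan: the CO2 level is
    non-zero at rest, so a causal HRF convolution needs more than a kernel
    length of edge-held history for its output to be transient-free over
    every shifted sampling window.
    """
    if grid_dt <= 0:
        raise ValueError("grid_dt must be positive")
    times = np.asarray(trace.times, dtype=float)
    values = np.asarray(trace.values, dtype=float)
    coverage = min(times[-1], total_duration) - max(times[0], 0.0)
    if coverage < 0.5 * total_duration:
        raise ValueError(
            f"trace covers {coverage:.1f} s of a {total_duration:.1f} s scan "
            "(need at least half)"
        )
    t0 = -float(pad + warmup)
    n = int(round((total_duration + 2 * pad + warmup) / grid_dt)) + 1
    t = t0 + np.arange(n) * grid_dt
    return GridSeries(t0=t0, dt=float(grid_dt), values=np.interp(t, times, values))


def convolve(source: GridSeries, kernel: HRFKernel | None) -> GridSeries:
    """Causal linear convolution with a sampled HRF; ``None`` is identity.

    The output lives on the source grid (cropped to its support).  A
    unit-sum kernel therefore preserves plateau amplitudes.
    """
    if kernel is None:
        return source
    if abs(kernel.dt - source.dt) > 1e-9:
        raise ValueError(
            f"kernel dt {kernel.dt} does not match source dt {source.dt}"
        )
    out = np.convolve(source.values, kernel.samples)[: source.values.size]
    return GridSeries(t0=source.t0, dt=source.dt, values=out)


def shift_and_sample(
    series: GridSeries,
    lag: float,
    tr: float,
    n_vols: int,
    *,
    normalize: bool = True,
) -> np.ndarray:
    """Delay ``series`` by ``lag`` s, sample at k*TR, min-max normalize.

    The sampled value at volume k is ``series(k*TR - lag)`` (positive lag =
    later response).  Sample times must fall inside the padded support of the
    series.  Normalization maps the column exactly onto [0, 1].
    """
    if tr <= 0 or n_vols < 2:
        raise ValueError("need tr > 0 and n_vols >= 2")
    t = np.arange(n_vols) * tr - lag
    if t[0] < series.t0 - 1e-9 or t[-1] > series.t_end + 1e-9:
        raise ValueError(
            f"lag {lag:g} s exceeds the series padding "
            f"([{series.t0:g}, {series.t_end:g}] s)"
        )
    x = series.at(t)
    if not normalize:
        return x
    lo, hi = x.min(), x.max()
    if hi - lo <= 0:
        raise ValueError("degenerate regressor: constant after sampling")
    return (x - lo) / (hi - lo)


def extend_motion_params(motion6: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Expand 6 rigid-body columns to the 24-parameter set.

    Order: the 6 parameters, their 6 backward-difference temporal
    derivatives (first row 0), the 6 squares, and the 6 squared derivatives.
    """
    m = np.asarray(motion6, dtype=float)
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValueError("motion6 must be (volumes, 6)")
    d = np.zeros_like(m)
    d[1:] = np.diff(m, axis=0)
    out = np.hstack([m, d, m**2, d**2])
    base = ["tx", "ty", "tz", "rx", "ry", "rz"]
    names = (
        base
        + [f"d_{b}" for b in base]
        + [f"{b}_sq" for b in base]
        + [f"d_{b}_sq" for b in base]
    )
    return out, names


def detect_motion_outliers(
    bold: BoldDataset,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flag volumes whose RMS difference from the middle volume is extreme.

    The metric for volume t is the root mean square, over in-brain voxels, of
    ``vol_t - vol_ref`` with the reference being the middle volume.  Volumes
    with metric above Q75 + 1.5*IQR are outliers; each gets a unit indicator
    (spike) column.

    Returns
    -------
    spikes : (T, n_outliers) indicator matrix
    indices : outlier volume indices
    metric : (T,) RMS-difference metric
    """
    if bold.n_volumes < 3:
        raise ValueError("need at least 3 volumes")
    mask = bold.brain_mask
    if not mask.any():
        raise ValueError("brain mask is empty")
    series = bold.data[mask]  # (V, T)
    ref = series[:, bold.n_volumes // 2]
    metric = np.sqrt(((series - ref[:, None]) ** 2).mean(axis=0))
    q25, q75 = np.percentile(metric, [25, 75])
    threshold = q75 + 1.5 * (q75 - q25)
    indices = np.flatnonzero(metric > threshold)
    spikes = np.zeros((bold.n_volumes, indices.size))
    spikes[indices, np.arange(indices.size)] = 1.0
    return spikes, indices, metric


def build_confounds(
    bold: BoldDataset, *, with_outliers: bool = True
) -> ConfoundMatrix:
    """24 extended motion parameters plus spike regressors for one run."""
    n = bold.n_volumes
    if bold.motion6 is None:
        motion = np.zeros((n, 6))
        warnings.warn("no motion table attached; motion confounds are zero")
    else:
        motion = bold.motion6
    cols, names = extend_motion_params(motion)
    if with_outliers:
        spikes, indices, _ = detect_motion_outliers(bold)
        cols = np.hstack([cols, spikes])
        names = names + [f"spike_{i:03d}" for i in indices]
    return ConfoundMatrix(columns=cols, names=tuple(names))
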