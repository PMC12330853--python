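"""Synthetic breath-hold data with known ground truth.

Everything downstream of acquisition is testable against this module: it
generates the paradigm (see :mod:`bhcvr.paradigm`), a capnograph trace with
end-tidal peaks and the post-hold PetCO2 overshoot, rigid-body motion
parameters, and a 4-D BOLD run whose per-voxel CVR amplitude and
hemodynamic lag are known exactly.

Forward model per voxel i::

    y_i(t_k) = mu_i * (1 + c_i * (x_i[k] - mean(x_i))) + drift + motion + noise

where ``c_i = cvr_i * dPetCO2 / 100`` and ``x_i`` is the high-resolution
model regressor delayed by the voxel's true lag, sampled at the volume
times and min-max normalized — exactly the candidate-column construction of
:func:`bhcvr.design.shift_and_sample`.  Centering ``x_i`` keeps the temporal
mean equal to ``mu_i``, so the mean-normalized CVR definition inverts the
forward model exactly in the noiseless case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import interpolate, stats

from .dataset import BoldDataset
from .design import GridSeries, shift_and_sample
from .paradigm import BHParadigm
from .physio import CapnoTrace

__all__ = [
    "GroundTruth",
    "SimulatedCapnograph",
    "simulate_capnograph",
    "simulate_motion",
    "make_ground_truth",
    "simulate_bold",
]

TISSUE_BACKGROUND, TISSUE_GM, TISSUE_WM = 0, 1, 2


@dataclass(frozen=True)
class SimulatedCapnograph:
    """A simulated capnograph trace plus its generating truth."""

    trace: CapnoTrace
    peak_times: np.ndarray    # exact end-tidal sample times (on the grid)
    peak_values: np.ndarray   # noiseless end-tidal values, mmHg
    baseline_petco2: float
    delta: float

    def ideal_petco2(self, grid_dt: float = 0.1, pad: float = 64.0) -> GridSeries:
        """Noiseless end-tidal course: PCHIP through the true peaks.

        Padded by ``pad`` s of edge-held values on both sides so that a
        causal HRF convolution has warmed up before the scan window (the
        resting CO2 level is non-zero, so zero prehistory would inject a
        spurious onset ramp).
        """
        f = interpolate.PchipInterpolator(self.peak_times, self.peak_values)
        t0 = self.peak_times[0] - pad
        n = int(np.floor((self.peak_times[-1] + pad - t0) / grid_dt)) + 1
        t = t0 + np.arange(n) * grid_dt
        inside = np.clip(t, self.peak_times[0], self.peak_times[-1])
        return GridSeries(t0=float(t0), dt=float(grid_dt), values=f(inside))


@dataclass
class GroundTruth:
    """Per-voxel simulation truth.

    ``tissue_label`` codes: 0 background, 1 GM, 2 WM.  Background voxels
    have zero CVR by construction.
    """

    cvr_true: np.ndarray          # %/mmHg
    lag_true: np.ndarray          # seconds
    tissue_label: np.ndarray      # int codes
    mean_signal: np.ndarray       # arbitrary scanner units
    delta_petco2_true: float      # mmHg

    def __post_init__(self) -> None:
        shape = self.tissue_label.shape
        for name in ("cvr_true", "lag_true", "mean_signal"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} shape {arr.shape} != {shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be finite")
            setattr(self, name, arr)
        if np.any(self.cvr_true[self.tissue_label == TISSUE_BACKGROUND] != 0):
            raise ValueError("background voxels must have cvr_true = 0")

    @property
    def brain_mask(self) -> np.ndarray:
        return self.tissue_label != TISSUE_BACKGROUND

    @property
    def gm_mask(self) -> np.ndarray:
        return self.tissue_label == TISSUE_GM

    @property
    def wm_mask(self) -> np.ndarray:
        return self.tissue_label == TISSUE_WM


def simulate_capnograph(
    paradigm: BHParadigm,
    baseline_petco2: float = 38.0,
    delta: float = 8.0,
    noise_sd: float = 0.0,
    seed: int | None = 0,
    *,
    fs: float = 10.0,
    inspired_level: float = 4.0,
    hold_tau: float = 3.0,
    n_recovery: int = 3,
    recovery_decay: float = 0.5,
    peak_frac: float = 0.7,
) -> SimulatedCapnograph:
    """Simulate a nasal-cannula CO2 trace for a breath-hold run.

    During cued breathing each respiratory cycle ramps from the inspired
    level (~``inspired_level`` mmHg) to an end-tidal plateau at
    ``baseline_petco2``.  During holds there is no airflow and the reading
    decays toward zero, so no end-tidal peaks occur.  The first exhalation
    after each hold peaks at ``baseline_petco2 + delta`` and the next
    ``n_recovery - 1`` breaths relax geometrically (factor
    ``recovery_decay``) back to baseline — within a couple of breaths, as in
    real recordings.

    End-tidal anchor times are snapped to the sampling grid, so the
    noiseless trace attains the stored ``peak_values`` exactly at
    ``peak_times``.
    """
    if delta < 0:
        raise ValueError("delta must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if baseline_petco2 <= inspired_level:
        raise ValueError("baseline_petco2 must exceed the inspired level")
    if fs <= 2 * paradigm.breathing_rate:
        raise ValueError("fs must resolve the breathing cycle")

    period = 1.0 / paradigm.breathing_rate
    total = paradigm.total_duration

    def snap(t: float) -> float:
        return round(t * fs) / fs

    # Breathing segments between holds.
    holds = paradigm.hold_intervals()
    segments: list[tuple[float, float, bool]] = []  # (start, end, after_hold)
    prev, after = 0.0, False
    for start, end in holds:
        segments.append((prev, start, after))
        prev, after = end, True
    segments.append((prev, total, after))

    anchor_t: list[float] = []
    anchor_v: list[float] = []
    peak_t: list[float] = []
    peak_v: list[float] = []

    def add_anchor(t: float, v: float) -> None:
        t = snap(t)
        if anchor_t and t <= anchor_t[-1] + 1e-12:
            return
        anchor_t.append(t)
        anchor_v.append(v)

    for seg_start, seg_end, after_hold in segments:
        # hold decay anchors precede this segment (except at run start)
        if after_hold:
            hold_start = seg_start - paradigm.hold_duration
            for tt in np.arange(hold_start, seg_start, 1.0):
                add_anchor(tt, inspired_level * np.exp(-(tt - hold_start) / hold_tau))
            add_anchor(seg_start, inspired_level * np.exp(-paradigm.hold_duration / hold_tau))
        breath = 0
        t0 = seg_start
        while t0 + period <= seg_end + 1e-9:
            if after_hold and breath < n_recovery:
                target = baseline_petco2 + delta * recovery_decay**breath
            else:
                target = baseline_petco2
            add_anchor(t0, inspired_level)
            tp = snap(t0 + peak_frac * period)
            add_anchor(tp, target)
            peak_t.append(tp)
            peak_v.append(target)
            breath += 1
            t0 += period
        add_anchor(t0, inspired_level)

    if anchor_t[-1] < total:
        add_anchor(total, anchor_v[-1])

    n = int(round(total * fs)) + 1
    t = np.arange(n) / fs
    co2 = interpolate.PchipInterpolator(anchor_t, anchor_v)(t)
    if noise_sd > 0:
        if seed is None:
            raise ValueError("seed is required when noise_sd > 0")
        rng = np.random.default_rng(seed)
        co2 = co2 + rng.normal(0.0, noise_sd, size=n)
    co2 = np.clip(co2, 0.0, None)
    return SimulatedCapnograph(
        trace=CapnoTrace(time=t, co2=co2),
        peak_times=np.asarray(peak_t),
        peak_values=np.asarray(peak_v),
        baseline_petco2=float(baseline_petco2),
        delta=float(delta),
    )


def simulate_motion(
    n_vols: int,
    amplitude: float = 0.15,
    seed: int = 0,
    *,
    n_spikes: int = 2,
    spike_scale: float = 6.0,
) -> np.ndarray:
    """Six rigid-body motion columns: slow random walk plus brief spikes.

    ``amplitude`` sets the walk's end-of-run standard deviation (mm for the
    translation columns; the rotation columns share the scale in mrad).
    """
    rng = np.random.default_rng(seed)
    walk = np.cumsum(rng.normal(0.0, amplitude / np.sqrt(n_vols), (n_vols, 6)), axis=0)
    for _ in range(n_spikes):
        k = int(rng.integers(1, n_vols))
        walk[k] += rng.normal(0.0, spike_scale * amplitude, 6)
    return walk


def make_ground_truth(
    shape: tuple[int, int, int] = (20, 20, 10),
    *,
    gm_cvr: float = 0.45,
    wm_cvr: float = 0.20,
    gm_lag: float = -0.2,
    wm_lag: float = 0.2,
    lag_sd: float = 1.0,
    lag_range: tuple[float, float] = (-3.0, 3.0),
    lag_grid: float | None = None,
    gm_mean: float = 7905.0,
    wm_mean: float = 7100.0,
    bg_mean: float = 50.0,
    delta_petco2: float = 8.0,
    seed: int = 0,
) -> GroundTruth:
    """Build a box-in-box phantom with GM shell and WM core.

    Tissue CVR defaults (GM 0.45, WM 0.20 %/mmHg) and lag offsets (GM -0.2 s,
    WM +0.2 s) sit inside the ranges reported for healthy adults.  Per-voxel
    lags are drawn from tissue-specific Gaussians truncated to ``lag_range``;
    with ``lag_grid`` set they are snapped to that grid (e.g. 1.0 s for exact
    recovery tests against the integer lag sweep).
    """
    rng = np.random.default_rng(seed)
    nx, ny, nz = shape
    tissue = np.zeros(shape, dtype=int)
    bx, by, bz = max(1, nx // 10), max(1, ny // 10), max(1, nz // 10)
    brain = np.zeros(shape, dtype=bool)
    brain[bx : nx - bx, by : ny - by, bz : nz - bz] = True
    wx, wy, wz = nx // 3, ny // 3, nz // 3
    wm = np.zeros(shape, dtype=bool)
    wm[wx : nx - wx, wy : ny - wy, wz : nz - wz] = True
    wm &= brain
    tissue[brain] = TISSUE_GM
    tissue[wm] = TISSUE_WM

    cvr = np.zeros(shape)
    cvr[tissue == TISSUE_GM] = gm_cvr
    cvr[tissue == TISSUE_WM] = wm_cvr

    lag = np.zeros(shape)
    lo, hi = lag_range
    for code, mu in ((TISSUE_GM, gm_lag), (TISSUE_WM, wm_lag)):
        m = tissue == code
        a, b = (lo - mu) / lag_sd, (hi - mu) / lag_sd
        lag[m] = stats.truncnorm.rvs(
            a, b, loc=mu, scale=lag_sd, size=int(m.sum()), random_state=rng
        )
    if lag_grid is not None:
        lag = np.clip(np.round(lag / lag_grid) * lag_grid, lo, hi)

    mean = np.full(shape, bg_mean)
    mean[tissue == TISSUE_GM] = gm_mean
    mean[tissue == TISSUE_WM] = wm_mean
    return GroundTruth(
        cvr_true=cvr,
        lag_true=lag,
        tissue_label=tissue,
        mean_signal=mean,
        delta_petco2_true=float(delta_petco2),
    )


def simulate_bold(
    paradigm: BHParadigm,
    truth: GroundTruth,
    regressor_truth: GridSeries,
    tr: float = 1.26,
    *,
    n_vols: int | None = None,
    noise_sd: float = 0.0,
    drift_amp: float = 0.0,
    drift_period: float = 128.0,
    motion: np.ndarray | None = None,
    motion_amp: float = 0.0,
    seed: int | None = 0,
    voxel_size: float = 2.2,
) -> BoldDataset:
    """Generate a 4-D BOLD run from the ground truth.

    ``regressor_truth`` is the high-resolution model source (e.g. the ideal
    PetCO2 course convolved with an HRF); each voxel sees it delayed by its
    true lag.  ``noise_sd``, ``drift_amp`` and ``motion_amp`` are fractions
    of the voxel mean signal; drift is a slow cosine with period
    ``drift_period`` s (> detrend cutoff removes it).
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    if n_vols is None:
        n_vols = paradigm.n_volumes(tr)
    shape = truth.tissue_label.shape
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape != (n_vols, 6):
            raise ValueError(
                f"motion must be ({n_vols}, 6), got {motion.shape}"
            )

    stochastic = noise_sd > 0 or drift_amp > 0 or motion_amp > 0
    if stochastic and seed is None:
        raise ValueError("seed is required for a stochastic simulation")
    rng = np.random.default_rng(seed)

    times = np.arange(n_vols) * tr
    data = np.empty(shape + (n_vols,))
    flat = data.reshape(-1, n_vols)
    mean_flat = truth.mean_signal.reshape(-1)
    cvr_flat = truth.cvr_true.reshape(-1)
    lag_flat = truth.lag_true.reshape(-1)
    brain_flat = truth.brain_mask.reshape(-1)

    flat[:] = mean_flat[:, None]
    idx = np.flatnonzero(brain_flat & (cvr_flat != 0))
    if idx.size:
        queries = times[None, :] - lag_flat[idx, None]
        x = np.interp(queries.ravel(), regressor_truth.times, regressor_truth.values)
        x = x.reshape(idx.size, n_vols)
        lo = x.min(axis=1, keepdims=True)
        hi = x.max(axis=1, keepdims=True)
        if np.any(hi - lo <= 0):
            raise ValueError("regressor_truth is constant over the scan window")
        x = (x - lo) / (hi - lo)
        xc = x - x.mean(axis=1, keepdims=True)
        c = cvr_flat[idx] * truth.delta_petco2_true / 100.0
        flat[idx] += mean_flat[idx, None] * c[:, None] * xc

    v_all = np.flatnonzero(brain_flat)
    if drift_amp > 0:
        phase = rng.uniform(0, 2 * np.pi, v_all.size)
        drift = np.cos(2 * np.pi * times[None, :] / drift_period + phase[:, None])
        flat[v_all] += mean_flat[v_all, None] * drift_amp * drift
    if motion_amp > 0:
        if motion is None:
            raise ValueError("motion_amp > 0 requires a motion table")
        mz = (motion - motion.mean(axis=0)) / (motion.std(axis=0) + 1e-12)
        w = rng.normal(0.0, 1.0, (v_all.size, 6))
        w /= np.linalg.norm(w, axis=1, keepdims=True)
        flat[v_all] += mean_flat[v_all, None] * motion_amp * (w @ mz.T)
    if noise_sd > 0:
        flat += mean_flat[:, None] * noise_sd * rng.standard_normal(flat.shape)

    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    return BoldDataset(
        data=data,
        tr=tr,
        brain_mask=truth.brain_mask,
        gm_mask=truth.gm_mask,
        wm_mask=truth.wm_mask,
        motion6=motion if motion is not None else np.zeros((n_vols, 6)),
        affine=affine,
    )
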