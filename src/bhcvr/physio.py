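"""End-tidal CO2 processing.

A capnograph samples the CO2 partial pressure at the nostril.  Only the
values at the end of each exhalation (the end-tidal peaks, PetCO2)
approximate arterial CO2, so the processing chain is: correct the sampling
tube delay, detect the exhalation-end peaks, interpolate them onto a uniform
grid, detrend, and derive the breath-hold-induced PetCO2 increase (ΔPetCO2)
that calibrates CVR in %/mmHg.

ΔPetCO2 rule: for each hold, take the first end-tidal peak after the hold
ends (the recovery exhalation carries the accumulated CO2) and subtract the
mean of the end-tidal values over the preceding baseline, then average
across holds.  The baseline window excludes the recovery interval right
after the previous hold, so a trial's ΔPetCO2 peak never contaminates the
next trial's baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import interpolate, signal

from .paradigm import BHParadigm

__all__ = [
    "CapnoTrace",
    "PetCO2Trace",
    "DeltaPetCO2",
    "correct_tube_delay",
    "detect_end_tidal_peaks",
    "interpolate_and_detrend",
    "compute_delta_petco2",
]

#: Internal uniform resampling step, seconds.  (A literature value of
#: "0.027 Hz" is below any plausible breathing rate and is treated as a
#: typo; 10 Hz comfortably resolves end-tidal peak timing.)
DEFAULT_GRID_DT = 0.1


@dataclass(frozen=True)
class CapnoTrace:
    """Raw capnograph samples: time (s, strictly increasing) and CO2 (mmHg)."""

    time: np.ndarray
    co2: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        c = np.asarray(self.co2, dtype=float)
        if t.ndim != 1 or t.shape != c.shape or t.size == 0:
            raise ValueError("time and co2 must be equal-length 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("co2 must be non-negative")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "co2", c)


@dataclass(frozen=True)
class PetCO2Trace:
    """Uniformly resampled, detrended end-tidal trace.

    ``values`` live on ``t0 + k*grid_dt``; ``peak_times``/``peak_values``
    record the detected exhalation-end samples of the *raw* trace (before
    interpolation and detrending) — these absolute mmHg values feed the
    ΔPetCO2 computation.
    """

    grid_dt: float
    t0: float
    values: np.ndarray
    peak_times: np.ndarray
    peak_values: np.ndarray
    tube_delay: float = 0.0

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) * self.grid_dt


@dataclass(frozen=True)
class DeltaPetCO2:
    """Per-trial and mean BH-induced PetCO2 increase, mmHg.

    Trials whose post-hold peak could not be found are NaN and excluded from
    the mean.
    """

    per_trial: np.ndarray
    mean: float


def correct_tube_delay(trace: CapnoTrace, delay: float) -> CapnoTrace:
    """Shift timestamps by -delay (gas transit through the sampling tube).

    Samples that land before t = 0 are dropped.
    """
    if delay < 0:
        raise ValueError("delay must be non-negative")
    if delay == 0:
        return trace
    t = trace.time - delay
    keep = t >= 0
    if not keep.any():
        raise ValueError("tube delay longer than the whole trace")
    return CapnoTrace(time=t[keep], co2=trace.co2[keep])


def detect_end_tidal_peaks(
    trace: CapnoTrace,
    min_period: float = 2.0,
    *,
    prominence_frac: float = 0.25,
) -> tuple[np.ndarray, np.ndarray]:
    """Detect exhalation-end maxima of the CO2 waveform.

    A sample is a peak if it is a local maximum with prominence at least
    ``prominence_frac`` times the trace's interquartile range (robust against
    cardiogenic ripples), and peaks closer than ``min_period`` s are thinned
    keeping the higher one.  During apneas the trace decays monotonically, so
    no peaks are produced there.  A constant trace yields no peaks.
    """
    if min_period <= 0:
        raise ValueError("min_period must be positive")
    co2 = trace.co2
    if co2.size < 3:
        return np.array([]), np.array([])
    iqr = float(np.subtract(*np.percentile(co2, [75, 25])))
    prominence = max(prominence_frac * iqr, 1e-12)
    idx, _ = signal.find_peaks(co2, prominence=prominence)
    if idx.size == 0:
        return np.array([]), np.array([])
    # Greedy thinning in time, highest peaks first.
    order = idx[np.argsort(co2[idx])[::-1]]
    kept: list[int] = []
    for i in order:
        if all(abs(trace.time[i] - trace.time[j]) >= min_period for j in kept):
            kept.append(i)
    kept_idx = np.sort(np.asarray(kept))
    return trace.time[kept_idx], co2[kept_idx]


def interpolate_and_detrend(
    peaks: tuple[np.ndarray, np.ndarray],
    grid_dt: float = DEFAULT_GRID_DT,
    cutoff: float = 100.0,
) -> PetCO2Trace:
    """Build the uniform PetCO2 trace from detected peaks.

    Piecewise-cubic (PCHIP) interpolation through the peaks onto a
    ``grid_dt`` grid spanning [first peak, last peak], followed by a
    second-order Butterworth high-pass at ``1/cutoff`` Hz applied
    forward-backward, with the original mean re-added (the absolute mmHg
    level is needed downstream).
    """
    times = np.asarray(peaks[0], dtype=float)
    values = np.asarray(peaks[1], dtype=float)
    if times.size < 2:
        raise ValueError("need at least 2 peaks to interpolate")
    if cutoff <= 0 or grid_dt <= 0:
        raise ValueError("cutoff and grid_dt must be positive")
    n = int(np.floor((times[-1] - times[0]) / grid_dt)) + 1
    grid = times[0] + np.arange(n) * grid_dt
    interp = interpolate.PchipInterpolator(times, values)(grid)

    fs = 1.0 / grid_dt
    wn = (1.0 / cutoff) / (fs / 2.0)
    sos = signal.butter(2, wn, btype="highpass", output="sos")
    filtered = signal.sosfiltfilt(sos, interp)
    filtered = filtered + (interp.mean() - filtered.mean())
    return PetCO2Trace(
        grid_dt=float(grid_dt),
        t0=float(times[0]),
        values=filtered,
        peak_times=times,
        peak_values=values,
    )


def compute_delta_petco2(
    trace: PetCO2Trace,
    paradigm: BHParadigm,
    search_window: float = 20.0,
    *,
    baseline_exclusion: float | None = None,
) -> DeltaPetCO2:
    """BH-induced PetCO2 increase per trial and averaged across trials.

    For hold k: ``per_trial[k]`` = (first end-tidal peak within
    ``search_window`` s after the hold ends) minus (mean end-tidal value over
    the cued-breathing window preceding the hold).  That window runs from the
    previous hold's end plus ``baseline_exclusion`` s (default:
    ``search_window``, so post-hold recovery breaths are excluded) — or the
    run start for the first trial — up to the hold onset.  Missing post-hold
    peaks are warned about, set to NaN and excluded from the mean.
    """
    if search_window <= 0:
        raise ValueError("search_window must be positive")
    if baseline_exclusion is None:
        baseline_exclusion = search_window
    pt, pv = trace.peak_times, trace.peak_values
    per_trial = np.full(paradigm.n_trials, np.nan)
    prev_end = None
    for k, (onset, end) in enumerate(paradigm.hold_intervals()):
        base_start = 0.0 if prev_end is None else prev_end + baseline_exclusion
        in_base = (pt >= base_start) & (pt < onset)
        post = (pt > end) & (pt <= end + search_window)
        if not in_base.any():
            raise ValueError(f"no baseline end-tidal samples before hold {k}")
        if not post.any():
            warnings.warn(
                f"no post-hold PetCO2 peak within {search_window:g} s of "
                f"hold {k}; trial excluded"
            )
        else:
            first_peak = pv[post][0]
            per_trial[k] = first_peak - pv[in_base].mean()
        prev_end = end
    if np.all(np.isnan(per_trial)):
        raise ValueError("no trial yielded a post-hold peak")
    return DeltaPetCO2(per_trial=per_trial, mean=float(np.nanmean(per_trial)))
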