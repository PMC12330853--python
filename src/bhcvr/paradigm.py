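"""Breath-hold task paradigms.

A breath-hold (BH) run alternates cued normal breathing at the subject's own
rate with voluntary end-expiration apneas.  The paradigm object records the
hold onsets and durations on the scanner clock; everything downstream (block
regressors, ΔPetCO2 baselines, simulation) is derived from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BHParadigm", "make_paradigm"]


@dataclass(frozen=True)
class BHParadigm:
    """Timing of a breath-hold run.

    Parameters
    ----------
    trial_onsets : ndarray of float
        Start time of each hold, seconds from the first volume.
    hold_duration : float
        Apnea duration in seconds (common to all trials).
    baseline_duration : float
        Duration of the cued-breathing interval immediately preceding each
        hold, seconds.
    total_duration : float
        Run length in seconds.
    breathing_rate : float
        Cued breathing rate during baseline, Hz.
    """

    trial_onsets: np.ndarray
    hold_duration: float
    baseline_duration: float
    total_duration: float
    breathing_rate: float = 0.25

    def __post_init__(self) -> None:
        onsets = np.asarray(self.trial_onsets, dtype=float)
        object.__setattr__(self, "trial_onsets", onsets)
        if onsets.ndim != 1 or onsets.size == 0:
            raise ValueError("trial_onsets must be a non-empty 1-D sequence")
        if np.any(np.diff(onsets) <= 0):
            raise ValueError("trial_onsets must be strictly increasing")
        if self.hold_duration <= 0 or self.baseline_duration <= 0:
            raise ValueError("durations must be positive")
        if self.breathing_rate <= 0:
            raise ValueError("breathing_rate must be positive")
        ends = onsets + self.hold_duration
        if onsets[0] < 0 or ends[-1] > self.total_duration + 1e-9:
            raise ValueError("hold intervals must lie within [0, total_duration]")
        if np.any(onsets[1:] < ends[:-1]):
            raise ValueError("hold intervals must not overlap")

    @property
    def n_trials(self) -> int:
        return int(self.trial_onsets.size)

    def hold_intervals(self) -> list[tuple[float, float]]:
        """[start, end) interval of each apnea, seconds."""
        return [
            (float(t), float(t + self.hold_duration)) for t in self.trial_onsets
        ]

    def n_volumes(self, tr: float) -> int:
        """Number of volumes acquired at repetition time ``tr``."""
        if tr <= 0:
            raise ValueError("tr must be positive")
        return int(np.floor(self.total_duration / tr))


def make_paradigm(
    n_trials: int = 4,
    hold: float = 15.0,
    baseline: float = 30.0,
    lead_in: float = 59.0,
    *,
    exhalation: float = 0.0,
    recovery: float = 0.0,
    trailing: float | None = None,
    breathing_rate: float = 0.25,
) -> BHParadigm:
    """Construct a periodic breath-hold paradigm.

    Each trial consists of ``baseline`` s of cued breathing, ``hold`` s of
    apnea and, optionally, an ``exhalation`` and ``recovery`` phase before the
    next trial's baseline.  The run opens with a ``lead_in`` interval
    (instructions plus initial rest) and closes with ``trailing`` seconds of
    free breathing (defaults to one baseline).

    The defaults reproduce a four-trial end-expiration layout: 15 s holds
    alternating with 30 s cued baselines, spanning a 269 s acquisition
    (213 volumes at TR = 1.26 s).

    Parameters
    ----------
    n_trials, hold, baseline, lead_in
        Trial count and phase durations in seconds.
    exhalation, recovery
        Optional post-hold phases; with 3 s and 11 s and a 24 s paced
        baseline this reproduces the 58 s trial span of paced-breathing
        protocols.
    trailing
        Final free-breathing interval; ``None`` means ``baseline``.
    breathing_rate
        Cued breathing rate in Hz.

    Returns
    -------
    BHParadigm
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    for name, value in (
        ("hold", hold),
        ("baseline", baseline),
    ):
        if value <= 0:
            raise ValueError(f"{name} must be positive")
    for name, value in (
        ("lead_in", lead_in),
        ("exhalation", exhalation),
        ("recovery", recovery),
    ):
        if value < 0:
            raise ValueError(f"{name} must be non-negative")
    if trailing is None:
        trailing = baseline
    elif trailing < 0:
        raise ValueError("trailing must be non-negative")

    span = baseline + hold + exhalation + recovery
    onsets = lead_in + np.arange(n_trials) * span + baseline
    last_end = onsets[-1] + hold + exhalation + recovery
    total = float(last_end + trailing)
    return BHParadigm(
        trial_onsets=onsets,
        hold_duration=float(hold),
        baseline_duration=float(baseline),
        total_duration=total,
        breathing_rate=float(breathing_rate),
    )
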