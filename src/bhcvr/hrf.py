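"""Hemodynamic response function bank.

The BOLD response to a hypercapnic stimulus is modelled by convolving the
stimulus time course with a gamma-shaped kernel.  Two shapes are supported:

* ``single`` — one gamma density (positive lobe only),
* ``double`` — a positive gamma minus a scaled, later gamma (undershoot).

The kernel is parametrized SPM-style by five numbers: ``p1`` time to positive
peak, ``p2`` time to undershoot, ``p3``/``p4`` dispersions of the two lobes
and ``p5`` the peak/undershoot amplitude ratio.  The delay and dispersion are
coupled — ``p3 = p1/6``, ``p4 = p3``, ``p2 = (8/3) p1``, ``p5 = 6`` — so a
single delay value between 3 and 11 s indexes the whole family; the canonical
member has ``p1 = 6``.  Each gamma lobe is a Gamma density with shape
``delay/dispersion`` and scale ``dispersion`` (seconds), so the positive-lobe
mode sits at ``p1 - p3``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

__all__ = ["HRFParams", "HRFKernel", "make_params", "sample_kernel", "build_bank"]

DELAY_MIN = 3.0
DELAY_MAX = 11.0
DEFAULT_DELAYS = tuple(float(d) for d in range(3, 12))
SHAPES = ("single", "double")


@dataclass(frozen=True)
class HRFParams:
    p1: float
    p2: float
    p3: float
    p4: float
    p5: float
    shape: Literal["single", "double"]

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"shape must be one of {SHAPES}")
        if min(self.p1, self.p2, self.p3, self.p4, self.p5) <= 0:
            raise ValueError("HRF parameters must be positive")


@dataclass(frozen=True)
class HRFKernel:
    """A sampled, unit-sum HRF kernel on a uniform grid starting at t = 0."""

    dt: float
    samples: np.ndarray
    duration: float
    params: HRFParams

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.dt


def make_params(delay: float, shape: Literal["single", "double"]) -> HRFParams:
    """Parameters of the delay/dispersion-coupled HRF family.

    ``delay`` is the time to the positive peak ``p1`` in seconds and must lie
    in [3, 11]; the dispersion is scaled with it as ``p3 = delay/6`` and the
    undershoot timing follows as ``p2 = (8/3) delay``, ``p4 = p3``, ``p5 = 6``.
    """
    if not DELAY_MIN <= delay <= DELAY_MAX:
        raise ValueError(
            f"delay must be within [{DELAY_MIN:g}, {DELAY_MAX:g}] s, got {delay!r}"
        )
    p3 = delay / 6.0
    return HRFParams(
        p1=float(delay),
        p2=float(delay * 8.0 / 3.0),
        p3=p3,
        p4=p3,
        p5=6.0,
        shape=shape,
    )


def _analytic(params: HRFParams, t: np.ndarray) -> np.ndarray:
    """Un-normalized kernel: gamma density (minus scaled undershoot)."""
    vals = stats.gamma.pdf(t, a=params.p1 / params.p3, scale=params.p3)
    if params.shape == "double":
        vals = vals - stats.gamma.pdf(t, a=params.p2 / params.p4, scale=params.p4) / params.p5
    return vals


def sample_kernel(
    params: HRFParams,
    dt: float = 0.1,
    duration: float = 32.0,
    *,
    normalize: bool = True,
) -> HRFKernel:
    """Sample the kernel on ``t = 0, dt, ..., duration``.

    With ``normalize=True`` (default) the samples are scaled to unit sum so
    that convolution preserves the DC amplitude of the input; the
    un-normalized form integrates to 1 (single) or ``1 - 1/p5`` (double) over
    the positive half-line.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration < params.p2 + params.p4:
        raise ValueError(
            "duration must cover the undershoot tail "
            f"(need >= {params.p2 + params.p4:.1f} s)"
        )
    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt
    vals = _analytic(params, t)
    if normalize:
        total = vals.sum()
        if total <= 0:
            raise ValueError("kernel has non-positive sum; cannot normalize")
        vals = vals / total
    return HRFKernel(dt=float(dt), samples=vals, duration=float(duration), params=params)


def build_bank(
    shapes: Iterable[str] = SHAPES,
    delays: Sequence[float] = DEFAULT_DELAYS,
    dt: float = 0.1,
    duration: float = 32.0,
) -> list[HRFKernel]:
    """One kernel per (shape, delay), ordered shape-major then by delay."""
    shapes = [s for s in SHAPES if s in set(shapes)]
    delays = sorted(float(d) for d in delays)
    if not shapes or not delays:
        raise ValueError("shapes and delays must be non-empty")
    return [
        sample_kernel(make_params(d, s), dt=dt, duration=duration)
        for s in shapes
        for d in delays
    ]
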