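"""Minimal in-scope BOLD preprocessing.

Motion correction, distortion correction, registration and segmentation are
assumed done upstream (masks and motion tables are inputs).  What remains in
scope: temporal detrending, optional spatial smoothing, ROI mean series and
percent-signal-change utilities.

Detrending is implemented as a projection onto the orthogonal complement of
a slow drift basis (a linear term plus discrete cosines with frequencies
below 1/cutoff Hz), with the temporal mean preserved.  Unlike a recursive
filter this is exactly idempotent, and the same projection can be applied
to design-matrix columns so that filtering never biases the GLM estimates.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .dataset import BoldDataset

__all__ = [
    "drift_basis",
    "detrend_columns",
    "highpass_detrend",
    "smooth_spatial",
    "mean_roi_series",
    "percent_change",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548


def drift_basis(n_vols: int, tr: float, cutoff: float = 100.0) -> np.ndarray:
    """Orthonormal, zero-mean slow-drift basis (linear + DCT cosines).

    Cosine k has frequency k / (2 * n * TR); terms with frequency below
    1/cutoff Hz are included.  Columns are demeaned and orthonormalized, so
    projecting them out never changes a series' mean.
    """
    if cutoff <= 2 * tr:
        raise ValueError("cutoff must exceed 2*TR")
    t = np.arange(n_vols)
    cols = [t - t.mean()]
    k = 1
    while k / (2.0 * n_vols * tr) < 1.0 / cutoff:
        c = np.cos(np.pi * k * (t + 0.5) / n_vols)
        cols.append(c - c.mean())
        k += 1
    basis = np.column_stack(cols)
    q, _ = np.linalg.qr(basis)
    return q


def detrend_columns(x: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Project the drift basis out of column(s) ``x`` (mean preserved)."""
    x = np.asarray(x, dtype=float)
    one_d = x.ndim == 1
    if one_d:
        x = x[:, None]
    out = x - basis @ (basis.T @ x)
    return out[:, 0] if one_d else out


def highpass_detrend(bold: BoldDataset, cutoff: float = 100.0) -> BoldDataset:
    """Remove per-voxel slow drifts below 1/cutoff Hz, keeping the mean."""
    basis = drift_basis(bold.n_volumes, bold.tr, cutoff)
    flat = bold.data.reshape(-1, bold.n_volumes)
    out = flat - (flat @ basis) @ basis.T
    return bold.with_data(out.reshape(bold.data.shape))


def smooth_spatial(bold: BoldDataset, fwhm: float) -> BoldDataset:
    """Per-volume Gaussian smoothing with the given FWHM in millimetres.

    Sigma per axis is fwhm/2.3548 converted to voxels via the affine;
    boundaries are handled by reflection.  ``fwhm = 0`` is the identity.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm == 0:
        return bold
    sigma_vox = (fwhm * FWHM_TO_SIGMA) / bold.voxel_sizes
    out = ndimage.gaussian_filter(
        bold.data, sigma=tuple(sigma_vox) + (0.0,), mode="reflect"
    )
    return bold.with_data(out)


def mean_roi_series(bold: BoldDataset, mask: np.ndarray) -> np.ndarray:
    """Per-volume mean over the masked voxels."""
    mask = np.asarray(mask).astype(bool)
    if mask.shape != bold.spatial_shape:
        raise ValueError("mask shape does not match data")
    if not mask.any():
        raise ValueError("mask is empty")
    return bold.data[mask].mean(axis=0)


def percent_change(series: np.ndarray, mode: str = "bold") -> np.ndarray:
    """Percent signal change of a 1-D series.

    ``mode="bold"``: 100 * (x - mean) / mean — the conventional BOLD form.
    ``mode="zscore"``: 100 * (x - mean) / sd — unit-free, sd of 100.
    """
    x = np.asarray(series, dtype=float)
    mu = x.mean()
    if mode == "bold":
        if mu == 0:
            raise ValueError("series mean is zero; percent change undefined")
        denom = mu
    elif mode == "zscore":
        denom = x.std()
        if denom == 0:
            raise ValueError("constant series; z-scored change undefined")
    else:
        raise ValueError("mode must be 'bold' or 'zscore'")
    if np.ptp(x) == 0:
        raise ValueError("constant series; percent change degenerate")
    return 100.0 * (x - mu) / denom
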