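"""CVR and relative-lag maps, outlier thresholding, ROI summaries.

CVR in %/mmHg is the fitted response amplitude scaled to a unit CO2 change::

    CVR_i = beta_i / (mu_i * dPetCO2) * 100

with ``mu_i`` the voxel's temporal mean signal and ``dPetCO2`` the subject's
mean breath-hold PetCO2 increase.  The optimal-lag map is re-expressed
relative to its in-mask median (``Lag_rel``), and both maps are trimmed of
inadequately optimized extremes by percentile thresholds — (1, 90) for CVR,
(1, 99) for Lag_rel — which invalidate voxels without altering values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CVRMap",
    "LagRelMap",
    "compute_cvr",
    "compute_lag_rel",
    "percentile_threshold",
    "roi_summary",
]


@dataclass
class CVRMap:
    values: np.ndarray      # %/mmHg
    valid_mask: np.ndarray  # post-threshold validity


@dataclass
class LagRelMap:
    values: np.ndarray      # seconds, median-centred over the mask
    valid_mask: np.ndarray


def compute_cvr(
    beta_map: np.ndarray,
    mu_map: np.ndarray,
    delta_petco2: float,
    mask: np.ndarray,
) -> CVRMap:
    """Scale the fitted amplitude to %/mmHg (see module docstring).

    Voxels with non-positive mean signal are excluded with a warning.
    """
    if delta_petco2 <= 0:
        raise ValueError("delta_petco2 must be positive")
    mask = np.asarray(mask).astype(bool)
    mu = np.asarray(mu_map, dtype=float)
    valid = mask & (mu > 0)
    n_bad = int(mask.sum() - valid.sum())
    if n_bad:
        warnings.warn(f"excluding {n_bad} voxel(s) with non-positive mean signal")
    values = np.zeros_like(mu)
    values[valid] = beta_map[valid] / (mu[valid] * delta_petco2) * 100.0
    return CVRMap(values=values, valid_mask=valid)


def compute_lag_rel(lag_map: np.ndarray, mask: np.ndarray) -> LagRelMap:
    """Optimal lags minus their in-mask median (median of output is 0)."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    med = float(np.median(lag_map[mask]))
    values = np.zeros_like(np.asarray(lag_map, dtype=float))
    values[mask] = lag_map[mask] - med
    return LagRelMap(values=values, valid_mask=mask.copy())


def percentile_threshold(
    values: np.ndarray,
    mask: np.ndarray,
    low_pct: float,
    high_pct: float,
) -> np.ndarray:
    """Validity mask keeping in-mask voxels within [P_low, P_high].

    Percentiles use linear interpolation over the in-mask finite values;
    bounds are inclusive.  Values are never altered, only invalidated.
    """
    if not 0 <= low_pct < high_pct <= 100:
        raise ValueError("need 0 <= low < high <= 100")
    mask = np.asarray(mask).astype(bool)
    vals = np.asarray(values, dtype=float)
    in_mask = mask & np.isfinite(vals)
    if not in_mask.any():
        raise ValueError("no finite in-mask values to threshold")
    lo, hi = np.percentile(vals[in_mask], [low_pct, high_pct])
    return in_mask & (vals >= lo) & (vals <= hi)


def roi_summary(
    f_map: np.ndarray,
    cvr: CVRMap,
    lag_rel: LagRelMap,
    gm_mask: np.ndarray,
    wm_mask: np.ndarray,
    *,
    model: str = "",
    subject: str = "",
) -> pd.DataFrame:
    """Mean F, CVR and Lag_rel over valid voxels, per tissue ROI.

    One row per tissue; a tissue with no valid voxels gets NaN means and a
    warning.
    """
    rows = []
    for tissue, tmask in (("GM", gm_mask), ("WM", wm_mask)):
        tmask = np.asarray(tmask).astype(bool)
        if not tmask.any():
            raise ValueError(f"{tissue} mask is empty")

        def _mean(vals, valid):
            sel = tmask & valid
            if not sel.any():
                warnings.warn(f"no valid {tissue} voxels for {model}")
                return np.nan
            return float(vals[sel].mean())

        rows.append(
            {
                "subject": subject,
                "model": model,
                "tissue": tissue,
                "mean_f": _mean(f_map, np.ones_like(tmask)),
                "mean_cvr": _mean(cvr.values, cvr.valid_mask),
                "mean_lag_rel": _mean(lag_rel.values, lag_rel.valid_mask),
            }
        )
    return pd.DataFrame(rows)
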