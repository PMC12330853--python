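"""Lagged GLM: bulk-lag estimation, the 19-lag voxelwise sweep, and
partial-F lag selection.

The response latency to a breath hold varies across the brain, so a single
regressor cannot fit every voxel.  The approach: estimate one *bulk* lag per
run from the cross-correlation between the mean gray-matter BOLD series and
the model regressor (search ±15 s), then refit the GLM voxelwise with the
regressor shifted over ``bulk − 9 … bulk + 9`` s in 1 s steps (19
candidates) and keep, per voxel, the lag whose regressor attains the highest
partial F — the F of the regressor of interest alone, not of the full model.

Estimation is ordinary least squares; an optional single-pass AR(1)
pre-whitening (Cochrane–Orcutt with a pooled autocorrelation) is available
behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .dataset import BoldDataset
from .design import ConfoundMatrix, GridSeries, shift_and_sample

__all__ = [
    "LagGrid",
    "VoxelFitMaps",
    "make_lag_grid",
    "estimate_bulk_lag",
    "fit_voxel_glm",
    "sweep_and_select",
    "optimize_delay_and_lag",
]


@dataclass(frozen=True)
class LagGrid:
    """The candidate lags: bulk lag ± 9 s in 1 s steps (19 values)."""

    bulk_lag: float
    offsets: np.ndarray
    absolute_lags: np.ndarray


@dataclass
class VoxelFitMaps:
    """Per-voxel results of the lag sweep (defined inside the mask)."""

    beta: np.ndarray        # signal units
    partial_f: np.ndarray   # unitless, >= 0 (inf for an exact fit)
    lag_opt: np.ndarray     # seconds, one of the candidate lags
    dof: tuple[int, int]
    mask: np.ndarray
    delay_opt: np.ndarray | None = None


def make_lag_grid(
    bulk_lag: float, half_width: float = 9.0, step: float = 1.0
) -> LagGrid:
    offsets = np.arange(-half_width, half_width + step / 2, step)
    return LagGrid(
        bulk_lag=float(bulk_lag),
        offsets=offsets,
        absolute_lags=bulk_lag + offsets,
    )


def estimate_bulk_lag(
    gm_series: np.ndarray,
    regressor: GridSeries,
    tr: float,
    search: float = 15.0,
    step: float = 1.0,
) -> float:
    """Lag maximizing the correlation between the GM mean series and the
    shifted regressor, over ±``search`` s in ``step`` s increments.

    Exact ties resolve to the smallest |lag|; a boundary argmax is returned
    as-is with a warning (the sweep window may then be too narrow).
    """
    y = np.asarray(gm_series, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("gm_series is constant")
    times = np.arange(y.size) * tr
    lags = np.arange(-search, search + step / 2, step)
    best_lag, best_r = None, -np.inf
    for lag in sorted(lags, key=lambda L: (abs(L), L)):
        x = regressor.at(times - lag)
        if np.ptp(x) == 0:
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        if r > best_r:
            best_r, best_lag = r, float(lag)
    if best_lag is None:
        raise ValueError("regressor is constant at every candidate lag")
    if abs(abs(best_lag) - search) < 1e-9:
        warnings.warn(
            f"bulk lag hit the search boundary ({best_lag:+g} s); "
            "consider widening the search range"
        )
    return best_lag


def _drop_collinear(c: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Keep a maximal linearly independent subset of columns (QR pivoting)."""
    if c.shape[1] == 0:
        return c
    from scipy.linalg import qr

    _, r, piv = qr(c, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int((diag > tol * max(diag[0], 1.0)).sum()) if diag.size else 0
    if rank < c.shape[1]:
        warnings.warn(
            f"dropping {c.shape[1] - rank} collinear confound column(s)"
        )
    return c[:, np.sort(piv[:rank])]


def _nuisance_basis(
    n: int, confounds: ConfoundMatrix | None
) -> tuple[np.ndarray, int]:
    """Orthonormal basis of [intercept | confounds]; returns (Q, n_columns)."""
    cols = [np.ones((n, 1))]
    if confounds is not None:
        c = _drop_collinear(np.asarray(confounds.columns, dtype=float))
        if c.shape[0] != n:
            raise ValueError("confound rows must match series length")
        cols.append(c)
    c_all = np.hstack(cols)
    q, r = np.linalg.qr(c_all)
    keep = np.abs(np.diag(r)) > 1e-10 * max(abs(r[0, 0]), 1.0)
    return q[:, keep], int(keep.sum())


def fit_voxel_glm(
    y: np.ndarray,
    x: np.ndarray,
    confounds: ConfoundMatrix | None = None,
) -> tuple[float, float]:
    """OLS of one voxel on [x | confounds | intercept]; partial F for x.

    The partial F compares the full model against the reduced model without
    x: ``F = (RSS_reduced - RSS_full) / (RSS_full / (T - p_full))`` with one
    numerator degree of freedom.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = y.size
    q_nuis, q = _nuisance_basis(n, confounds)
    p_full = q + 1
    if n <= p_full:
        raise ValueError(f"insufficient degrees of freedom (T={n}, p={p_full})")
    x_full = np.column_stack([x, q_nuis])
    beta_full, _, _, _ = np.linalg.lstsq(x_full, y, rcond=None)
    rss_full = float(((y - x_full @ beta_full) ** 2).sum())
    resid_red = y - q_nuis @ (q_nuis.T @ y)
    rss_red = float((resid_red**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (rss_red - rss_full) / (rss_full / (n - p_full))
    if np.isnan(f):
        f = 0.0
    return float(beta_full[0]), float(max(f, 0.0))


def _pooled_ar1(resid: np.ndarray) -> float:
    """Pooled lag-1 autocorrelation of residuals (voxels x time)."""
    num = (resid[:, 1:] * resid[:, :-1]).sum()
    den = (resid**2).sum()
    return float(num / den) if den > 0 else 0.0


def _whiten(m: np.ndarray, rho: float) -> np.ndarray:
    """Cochrane–Orcutt transform along the last time axis."""
    out = m.copy()
    out[..., 1:] = m[..., 1:] - rho * m[..., :-1]
    out[..., 0] = np.sqrt(max(1.0 - rho**2, 1e-12)) * m[..., 0]
    return out


def _sweep_core(
    ydata: np.ndarray,
    columns: np.ndarray,
    q_nuis: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-candidate OLS via Frisch–Waugh.

    ydata: (V, T); columns: (L, T).  Returns beta, F arrays of shape (L, V)
    and the reduced-model RSS (V,).
    """
    n = ydata.shape[1]
    p_full = q_nuis.shape[1] + 1
    if n <= p_full:
        raise ValueError(f"insufficient degrees of freedom (T={n}, p={p_full})")
    y_r = ydata - (ydata @ q_nuis) @ q_nuis.T          # (V, T)
    rss_red = (y_r**2).sum(axis=1)                     # (V,)
    x_r = columns - (columns @ q_nuis) @ q_nuis.T      # (L, T)
    xx = (x_r**2).sum(axis=1)                          # (L,)
    if np.any(xx <= 1e-12 * n):
        raise ValueError(
            "a candidate regressor is degenerate after removing confounds"
        )
    xy = x_r @ y_r.T                                   # (L, V)
    beta = xy / xx[:, None]
    rss_full = np.maximum(rss_red[None, :] - beta * xy, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (rss_red[None, :] - rss_full) / (rss_full / (n - p_full))
    f = np.where(np.isnan(f), 0.0, f)
    return beta, np.maximum(f, 0.0), rss_red


def _select(
    f: np.ndarray, beta: np.ndarray, order: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Argmax over candidates with a deterministic tie order.

    ``order`` lists candidate indices by preference (first wins exact ties);
    selection requires a strict improvement in F.
    """
    n_vox = f.shape[1]
    best_f = np.full(n_vox, -np.inf)
    best_idx = np.zeros(n_vox, dtype=int)
    best_beta = np.zeros(n_vox)
    for idx in order:
        better = f[idx] > best_f
        best_f[better] = f[idx][better]
        best_idx[better] = idx
        best_beta[better] = beta[idx][better]
    return best_idx, best_beta, best_f


def _tie_order(offsets: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Preference order: smallest |offset| from bulk, then more negative lag."""
    return np.lexsort((lags, np.abs(offsets)))


def sweep_and_select(
    bold: BoldDataset,
    columns: np.ndarray,
    grid: LagGrid,
    confounds: ConfoundMatrix | None = None,
    mask: np.ndarray | None = None,
    *,
    prewhiten: bool = False,
) -> VoxelFitMaps:
    """Fit every candidate lag in every in-mask voxel; keep the argmax-F lag.

    ``columns`` is (n_lags, T), row i being the design column for
    ``grid.absolute_lags[i]``.  Exact F ties resolve to the smallest
    |offset| from the bulk lag, then the more negative lag.
    """
    columns = np.asarray(columns, dtype=float)
    if columns.ndim != 2 or columns.shape[0] != grid.absolute_lags.size:
        raise ValueError("columns must be (n_lags, T) matching the grid")
    if columns.shape[1] != bold.n_volumes:
        raise ValueError("candidate columns must match the series length")
    if mask is None:
        mask = bold.brain_mask
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")

    ydata = bold.data[mask]  # (V, T)
    q_nuis, _ = _nuisance_basis(bold.n_volumes, confounds)

    if prewhiten:
        resid = ydata - (ydata @ q_nuis) @ q_nuis.T
        rho = _pooled_ar1(resid)
        ydata = _whiten(ydata, rho)
        columns = _whiten(columns, rho)
        q_nuis, _ = np.linalg.qr(_whiten(q_nuis.T, rho).T)

    beta, f, _ = _sweep_core(ydata, columns, q_nuis)
    order = _tie_order(grid.offsets, grid.absolute_lags)
    best_idx, best_beta, best_f = _select(f, beta, order)

    shape = bold.spatial_shape
    beta_map = np.zeros(shape)
    f_map = np.zeros(shape)
    lag_map = np.zeros(shape)
    beta_map[mask] = best_beta
    f_map[mask] = best_f
    lag_map[mask] = grid.absolute_lags[best_idx]
    dof = (1, bold.n_volumes - (q_nuis.shape[1] + 1))
    return VoxelFitMaps(
        beta=beta_map, partial_f=f_map, lag_opt=lag_map, dof=dof, mask=mask
    )


def optimize_delay_and_lag(
    bold: BoldDataset,
    banks: Mapping[float, np.ndarray],
    grid: LagGrid,
    confounds: ConfoundMatrix | None = None,
    mask: np.ndarray | None = None,
) -> VoxelFitMaps:
    """Joint argmax-F over (HRF delay, lag).

    ``banks`` maps each HRF delay to its (n_lags, T) candidate matrix.  The
    delay and lag estimates interact strongly; at realistic noise the
    estimated delays pile up at the extremes of the tested range, so this
    search is provided for diagnosis rather than recommended use.
    """
    if len(banks) < 2:
        raise ValueError("need at least 2 delays for a joint search")
    if mask is None:
        mask = bold.brain_mask
    mask = np.asarray(mask).astype(bool)
    ydata = bold.data[mask]
    q_nuis, _ = _nuisance_basis(bold.n_volumes, confounds)

    delays = sorted(banks)
    all_f, all_beta = [], []
    meta = []  # (delay, lag, offset)
    for d in delays:
        cols = np.asarray(banks[d], dtype=float)
        beta, f, _ = _sweep_core(ydata, cols, q_nuis)
        all_f.append(f)
        all_beta.append(beta)
        meta.extend((d, lag, off) for lag, off in zip(grid.absolute_lags, grid.offsets))
    f = np.vstack(all_f)
    beta = np.vstack(all_beta)
    meta_arr = np.asarray(meta)  # (n_cand, 3)
    order = np.lexsort((meta_arr[:, 0], meta_arr[:, 1], np.abs(meta_arr[:, 2])))
    best_idx, best_beta, best_f = _select(f, beta, order)

    shape = bold.spatial_shape
    out = VoxelFitMaps(
        beta=np.zeros(shape),
        partial_f=np.zeros(shape),
        lag_opt=np.zeros(shape),
        dof=(1, bold.n_volumes - (q_nuis.shape[1] + 1)),
        mask=mask,
        delay_opt=np.zeros(shape),
    )
    out.beta[mask] = best_beta
    out.partial_f[mask] = best_f
    out.lag_opt[mask] = meta_arr[best_idx, 1]
    out.delay_opt[mask] = meta_arr[best_idx, 0]
    return out
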