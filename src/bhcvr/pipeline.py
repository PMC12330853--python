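"""End-to-end orchestration: files in, CVR / lag maps and summaries out.

``run_pipeline`` wires the stages together for one subject: physio
processing (tube delay, peaks, interpolation/detrend, ΔPetCO2), BOLD
preprocessing (smoothing, drift removal), confound assembly, then — per
requested signal model — bulk-lag estimation, the 19-lag voxelwise sweep,
CVR and relative-lag maps with percentile thresholds, and ROI summaries.
The drift projection applied to the data is also applied to the regressor
and confound columns, so filtering cannot bias the fits.

``fit_model`` is the per-model core and is directly usable in memory
(no files) — the file-based entry point is a thin wrapper around it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dataset import BoldDataset
from .design import (
    MODEL_GRID,
    ConfoundMatrix,
    GridSeries,
    Regressor,
    build_block,
    build_confounds,
    build_petco2,
    convolve,
    shift_and_sample,
)
from .hrf import make_params, sample_kernel
from .io import read_bold, read_events, read_physio, write_nifti
from .lagged_glm import (
    LagGrid,
    VoxelFitMaps,
    estimate_bulk_lag,
    make_lag_grid,
    optimize_delay_and_lag,
    sweep_and_select,
)
from .maps import (
    CVRMap,
    LagRelMap,
    compute_cvr,
    compute_lag_rel,
    percentile_threshold,
    roi_summary,
)
from .paradigm import BHParadigm
from .physio import (
    PetCO2Trace,
    compute_delta_petco2,
    correct_tube_delay,
    detect_end_tidal_peaks,
    interpolate_and_detrend,
)
from .prep import (
    detrend_columns,
    drift_basis,
    highpass_detrend,
    mean_roi_series,
    smooth_spatial,
)

__all__ = ["RunConfig", "ModelResult", "fit_model", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of a single-subject run.

    Paths must exist at validation time.  Model settings default to the full
    six-model comparison with the canonical HRF delay of 6 s, a ±15 s bulk
    search and the ±9 s / 1 s voxelwise sweep.
    """

    bold: str
    brain_mask: str
    gm_mask: str
    wm_mask: str
    physio: str
    events: str
    motion: str | None = None
    out_dir: str | None = None
    tr: float = 1.26
    subject: str = "sub-01"

    regressor_types: tuple[str, ...] = ("PetCO2", "Block")
    convolutions: tuple[str, ...] = ("WoC", "CSg", "CDb")
    hrf_delay: float = 6.0
    hrf_dt: float = 0.1
    hrf_duration: float = 32.0
    grid_dt: float = 0.1
    lag_step: float = 1.0
    lag_halfwidth: float = 9.0
    bulk_search: float = 15.0
    detrend_cutoff: float = 100.0
    smooth_fwhm: float = 3.5
    tube_delay: float = 0.0
    min_peak_period: float = 2.0
    delta_search_window: float = 20.0
    cvr_percentiles: tuple[float, float] = (1.0, 90.0)
    lag_percentiles: tuple[float, float] = (1.0, 99.0)
    baseline_mean_cvr: bool = False
    prewhiten: bool = False
    joint_delay_search: bool = False
    joint_delays: tuple[float, ...] = tuple(float(d) for d in range(3, 12))
    seed: int | None = None

    def validate(self) -> None:
        required = {
            "bold": self.bold,
            "brain_mask": self.brain_mask,
            "gm_mask": self.gm_mask,
            "wm_mask": self.wm_mask,
            "physio": self.physio,
            "events": self.events,
        }
        if self.motion is not None:
            required["motion"] = self.motion
        missing = [f"{k} ({v})" for k, v in required.items() if not Path(v).exists()]
        if missing:
            raise FileNotFoundError("missing inputs: " + "; ".join(missing))
        for rt in self.regressor_types:
            if rt not in ("PetCO2", "Block"):
                raise ValueError(f"unknown regressor type {rt!r}")
        for conv in self.convolutions:
            if conv not in ("WoC", "CSg", "CDb"):
                raise ValueError(f"unknown convolution {conv!r}")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in (
            "regressor_types",
            "convolutions",
            "cvr_percentiles",
            "lag_percentiles",
            "joint_delays",
        ):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def content_hash(self) -> str:
        """Hash of the analysis-relevant settings (output location excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ModelResult:
    """Outputs of one (regressor type, convolution) model."""

    label: str
    bulk_lag: float
    grid: LagGrid
    fits: VoxelFitMaps
    cvr: CVRMap
    lag_rel: LagRelMap
    roi: pd.DataFrame
    qc: dict


def _model_source(
    regressor_type: str,
    convolution: str,
    paradigm: BHParadigm,
    petco2: PetCO2Trace,
    *,
    grid_dt: float,
    hrf_delay: float,
    hrf_dt: float,
    hrf_duration: float,
    pad: float,
) -> GridSeries:
    if regressor_type == "Block":
        source = build_block(paradigm, grid_dt, pad=pad)
    else:
        source = build_petco2(
            petco2, grid_dt, total_duration=paradigm.total_duration, pad=pad
        )
    if convolution == "WoC":
        return source
    shape = "single" if convolution == "CSg" else "double"
    kernel = sample_kernel(make_params(hrf_delay, shape), dt=hrf_dt, duration=hrf_duration)
    return convolve(source, kernel)


def _mu_map(
    bold: BoldDataset, paradigm: BHParadigm, *, baseline_only: bool, window: float
) -> np.ndarray:
    """Per-voxel normalization mean: whole time course, or baseline volumes.

    Baseline mode excludes volumes within [onset, onset + hold + window) of
    any trial — the holds and their recovery.
    """
    if not baseline_only:
        return bold.data.mean(axis=3)
    t = bold.frame_times
    keep = np.ones(t.size, dtype=bool)
    for onset, end in paradigm.hold_intervals():
        keep &= ~((t >= onset) & (t < end + window))
    if not keep.any():
        raise ValueError("no baseline volumes left for the baseline mean")
    return bold.data[..., keep].mean(axis=3)


def fit_model(
    bold: BoldDataset,
    paradigm: BHParadigm,
    petco2: PetCO2Trace,
    delta_petco2: float,
    regressor_type: str,
    convolution: str,
    *,
    confounds: ConfoundMatrix | None = None,
    hrf_delay: float = 6.0,
    hrf_dt: float = 0.1,
    hrf_duration: float = 32.0,
    grid_dt: float = 0.1,
    lag_step: float = 1.0,
    lag_halfwidth: float = 9.0,
    bulk_search: float = 15.0,
    detrend_cutoff: float | None = 100.0,
    cvr_percentiles: tuple[float, float] = (1.0, 90.0),
    lag_percentiles: tuple[float, float] = (1.0, 99.0),
    baseline_mean_cvr: bool = False,
    delta_search_window: float = 20.0,
    prewhiten: bool = False,
    subject: str = "",
) -> ModelResult:
    """Fit one signal model on an in-memory dataset (assumed detrended).

    ``detrend_cutoff`` controls the drift projection applied to the design
    columns so they match data that went through ``highpass_detrend``; pass
    ``None`` if the data were not detrended.
    """
    label = f"{regressor_type}-{convolution}"
    pad = bulk_search + lag_halfwidth
    source = _model_source(
        regressor_type,
        convolution,
        paradigm,
        petco2,
        grid_dt=grid_dt,
        hrf_delay=hrf_delay,
        hrf_dt=hrf_dt,
        hrf_duration=hrf_duration,
        pad=pad,
    )
    gm_series = mean_roi_series(bold, bold.gm_mask)
    bulk = estimate_bulk_lag(gm_series, source, bold.tr, search=bulk_search, step=lag_step)
    grid = make_lag_grid(bulk, half_width=lag_halfwidth, step=lag_step)

    basis = (
        drift_basis(bold.n_volumes, bold.tr, detrend_cutoff)
        if detrend_cutoff is not None
        else None
    )
    columns = np.empty((grid.absolute_lags.size, bold.n_volumes))
    regressors = []
    for i, lag in enumerate(grid.absolute_lags):
        col = shift_and_sample(source, lag, bold.tr, bold.n_volumes)
        regressors.append(
            Regressor(
                grid_dt=grid_dt,
                values_highres=source,
                values_tr=col,
                regressor_type=regressor_type,
                convolution=convolution,
                hrf_delay=None if convolution == "WoC" else hrf_delay,
                lag=float(lag),
            )
        )
        columns[i] = detrend_columns(col, basis) if basis is not None else col

    conf = confounds
    if conf is not None and basis is not None:
        conf = ConfoundMatrix(
            columns=detrend_columns(conf.columns, basis), names=conf.names
        )
    fits = sweep_and_select(bold, columns, grid, conf, prewhiten=prewhiten)

    mu = _mu_map(
        bold, paradigm, baseline_only=baseline_mean_cvr, window=delta_search_window
    )
    cvr = compute_cvr(fits.beta, mu, delta_petco2, bold.brain_mask)
    cvr_valid = percentile_threshold(cvr.values, cvr.valid_mask, *cvr_percentiles)
    cvr = CVRMap(values=cvr.values, valid_mask=cvr_valid)
    lag_rel = compute_lag_rel(fits.lag_opt, bold.brain_mask)
    lag_valid = percentile_threshold(lag_rel.values, lag_rel.valid_mask, *lag_percentiles)
    lag_rel = LagRelMap(values=lag_rel.values, valid_mask=lag_valid)

    roi = roi_summary(
        fits.partial_f,
        cvr,
        lag_rel,
        bold.gm_mask,
        bold.wm_mask,
        model=label,
        subject=subject,
    )
    half = grid.offsets.max()
    boundary = float(
        np.isclose(np.abs(fits.lag_opt[fits.mask] - bulk), half).mean()
    )
    qc = {
        "model": label,
        "bulk_lag_s": bulk,
        "boundary_fraction": boundary,
        "dof": list(fits.dof),
        "n_voxels": int(fits.mask.sum()),
    }
    return ModelResult(
        label=label,
        bulk_lag=bulk,
        grid=grid,
        fits=fits,
        cvr=cvr,
        lag_rel=lag_rel,
        roi=roi,
        qc=qc,
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run the full single-subject analysis described by ``config``.

    Returns a dict with per-model :class:`ModelResult`, the pooled ROI
    table, ΔPetCO2, and QC/provenance records; writes maps and tables under
    ``config.out_dir`` when set.
    """
    config.validate()

    bold = read_bold(
        config.bold,
        config.brain_mask,
        config.gm_mask,
        config.wm_mask,
        tr=config.tr,
        motion_path=config.motion,
    )
    paradigm = read_events(
        config.events, total_duration=bold.n_volumes * config.tr
    )
    capno = read_physio(config.physio)

    capno = correct_tube_delay(capno, config.tube_delay)
    peaks = detect_end_tidal_peaks(capno, config.min_peak_period)
    petco2 = interpolate_and_detrend(peaks, config.grid_dt, config.detrend_cutoff)
    delta = compute_delta_petco2(petco2, paradigm, config.delta_search_window)

    confounds = build_confounds(bold)
    n_outliers = sum(1 for n in confounds.names if n.startswith("spike_"))

    bold = smooth_spatial(bold, config.smooth_fwhm)
    bold = highpass_detrend(bold, config.detrend_cutoff)

    models = [
        (rt, conv)
        for rt, conv in MODEL_GRID
        if rt in config.regressor_types and conv in config.convolutions
    ]
    results: dict[str, ModelResult] = {}
    for rt, conv in models:
        res = fit_model(
            bold,
            paradigm,
            petco2,
            delta.mean,
            rt,
            conv,
            confounds=confounds,
            hrf_delay=config.hrf_delay,
            hrf_dt=config.hrf_dt,
            hrf_duration=config.hrf_duration,
            grid_dt=config.grid_dt,
            lag_step=config.lag_step,
            lag_halfwidth=config.lag_halfwidth,
            bulk_search=config.bulk_search,
            detrend_cutoff=config.detrend_cutoff,
            cvr_percentiles=config.cvr_percentiles,
            lag_percentiles=config.lag_percentiles,
            baseline_mean_cvr=config.baseline_mean_cvr,
            delta_search_window=config.delta_search_window,
            prewhiten=config.prewhiten,
            subject=config.subject,
        )
        res.qc.update(
            delta_petco2_mmHg=delta.mean, n_motion_outliers=n_outliers
        )
        results[res.label] = res

    joint = None
    if config.joint_delay_search:
        joint = _joint_delay_search(bold, paradigm, petco2, confounds, config)

    roi_table = pd.concat([r.roi for r in results.values()], ignore_index=True)
    provenance = {
        "bhcvr_version": __version__,
        "numpy_version": np.__version__,
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "delta_petco2_per_trial": [float(v) for v in delta.per_trial],
        "delta_petco2_mean": delta.mean,
        "n_motion_outliers": n_outliers,
    }
    out = {
        "models": results,
        "roi_table": roi_table,
        "delta_petco2": delta,
        "provenance": provenance,
        "joint": joint,
    }
    if config.out_dir is not None:
        _write_outputs(Path(config.out_dir), config, bold, out)
    return out


def _joint_delay_search(bold, paradigm, petco2, confounds, config: RunConfig):
    """Optional joint (delay, lag) optimization for the convolved models."""
    basis = drift_basis(bold.n_volumes, bold.tr, config.detrend_cutoff)
    conf = ConfoundMatrix(
        columns=detrend_columns(confounds.columns, basis), names=confounds.names
    )
    pad = config.bulk_search + config.lag_halfwidth
    out = {}
    for rt in config.regressor_types:
        for conv in [c for c in config.convolutions if c != "WoC"]:
            # bulk lag from the canonical delay
            canonical = _model_source(
                rt,
                conv,
                paradigm,
                petco2,
                grid_dt=config.grid_dt,
                hrf_delay=config.hrf_delay,
                hrf_dt=config.hrf_dt,
                hrf_duration=config.hrf_duration,
                pad=pad,
            )
            gm_series = mean_roi_series(bold, bold.gm_mask)
            bulk = estimate_bulk_lag(
                gm_series, canonical, bold.tr, config.bulk_search, config.lag_step
            )
            grid = make_lag_grid(bulk, config.lag_halfwidth, config.lag_step)
            banks = {}
            for d in config.joint_delays:
                src = _model_source(
                    rt,
                    conv,
                    paradigm,
                    petco2,
                    grid_dt=config.grid_dt,
                    hrf_delay=d,
                    hrf_dt=config.hrf_dt,
                    hrf_duration=config.hrf_duration,
                    pad=pad,
                )
                cols = np.stack(
                    [
                        detrend_columns(
                            shift_and_sample(src, lag, bold.tr, bold.n_volumes),
                            basis,
                        )
                        for lag in grid.absolute_lags
                    ]
                )
                banks[d] = cols
            out[f"{rt}-{conv}"] = optimize_delay_and_lag(bold, banks, grid, conf)
    return out


def _write_outputs(out_dir: Path, config: RunConfig, bold, results: dict) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    sub = config.subject
    aff = bold.affine
    qc_all = {}
    for label, res in results["models"].items():
        tag = label.replace("-", "")
        write_nifti(out_dir / f"{sub}_model-{tag}_beta.nii", res.fits.beta, aff)
        f_safe = np.nan_to_num(res.fits.partial_f, posinf=np.finfo(np.float64).max)
        write_nifti(out_dir / f"{sub}_model-{tag}_partialF.nii", f_safe, aff)
        write_nifti(out_dir / f"{sub}_model-{tag}_lag.nii", res.fits.lag_opt, aff)
        write_nifti(out_dir / f"{sub}_model-{tag}_cvr.nii", res.cvr.values, aff)
        write_nifti(
            out_dir / f"{sub}_model-{tag}_cvrmask.nii",
            res.cvr.valid_mask.astype(float),
            aff,
        )
        write_nifti(out_dir / f"{sub}_model-{tag}_lagrel.nii", res.lag_rel.values, aff)
        write_nifti(
            out_dir / f"{sub}_model-{tag}_lagrelmask.nii",
            res.lag_rel.valid_mask.astype(float),
            aff,
        )
        qc_all[label] = res.qc
    results["roi_table"].to_csv(
        out_dir / f"{sub}_roi_summary.tsv", sep="\t", index=False, float_format="%.8g"
    )
    with open(out_dir / f"{sub}_qc.json", "w") as fh:
        json.dump(qc_all, fh, indent=2)
    with open(out_dir / f"{sub}_provenance.json", "w") as fh:
        json.dump(results["provenance"], fh, indent=2)
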