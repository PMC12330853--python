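"""Readers, writers and the synthetic-dataset bundle.

File conventions follow BIDS-flavoured naming without claiming derivatives
compliance: 4-D BOLD and 3-D masks as NIfTI, events as TSV
(onset/duration/trial_type), physio as TSV (time/co2), motion as a 6-column
TSV, and JSON for configuration and ground-truth metadata.  Pipeline NIfTI
outputs default to uncompressed ``.nii`` so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .dataset import BoldDataset
from .paradigm import BHParadigm, make_paradigm
from .physio import CapnoTrace

__all__ = [
    "read_nifti",
    "write_nifti",
    "read_events",
    "write_events",
    "read_physio",
    "write_physio",
    "read_motion",
    "write_motion",
    "read_bold",
    "SimulateConfig",
    "simulate_dataset",
    "write_simulation",
]


def write_nifti(path: str | Path, data: np.ndarray, affine: np.ndarray) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), np.asarray(affine))
    nib.save(img, str(path))
    return path


def read_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), np.asarray(img.affine)


def write_events(path: str | Path, paradigm: BHParadigm) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "onset": paradigm.trial_onsets,
            "duration": np.full(paradigm.n_trials, paradigm.hold_duration),
            "trial_type": ["breathhold"] * paradigm.n_trials,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path


def read_events(
    path: str | Path,
    total_duration: float,
    breathing_rate: float = 0.25,
) -> BHParadigm:
    """Reconstruct the paradigm from an events table.

    The baseline duration is inferred from the inter-trial spacing (or the
    first onset for a single trial); ``total_duration`` must be supplied
    (typically n_volumes * TR) since an events file does not record it.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("onset", "duration", "trial_type"):
        if col not in df.columns:
            raise ValueError(f"events file {path} is missing column '{col}'")
    bh = df[df["trial_type"] == "breathhold"].sort_values("onset")
    if bh.empty:
        raise ValueError(f"events file {path} has no breathhold trials")
    onsets = bh["onset"].to_numpy(dtype=float)
    durations = bh["duration"].to_numpy(dtype=float)
    if np.ptp(durations) > 1e-6:
        raise ValueError("unequal hold durations are not supported")
    hold = float(durations[0])
    if onsets.size > 1:
        baseline = float(onsets[1] - (onsets[0] + hold))
    else:
        baseline = float(onsets[0]) if onsets[0] > 0 else hold
    return BHParadigm(
        trial_onsets=onsets,
        hold_duration=hold,
        baseline_duration=baseline,
        total_duration=float(total_duration),
        breathing_rate=breathing_rate,
    )


def write_physio(path: str | Path, trace: CapnoTrace) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time": trace.time, "co2": trace.co2}).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
    return path


def read_physio(path: str | Path) -> CapnoTrace:
    df = pd.read_csv(path, sep="\t")
    for col in ("time", "co2"):
        if col not in df.columns:
            raise ValueError(f"physio file {path} is missing column '{col}'")
    return CapnoTrace(
        time=df["time"].to_numpy(dtype=float), co2=df["co2"].to_numpy(dtype=float)
    )


def write_motion(path: str | Path, motion6: np.ndarray) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = ["tx", "ty", "tz", "rx", "ry", "rz"]
    pd.DataFrame(np.asarray(motion6, dtype=float), columns=cols).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )
    return path


def read_motion(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != 6:
        raise ValueError(f"motion file {path} must have 6 columns")
    return df.to_numpy(dtype=float)


def read_bold(
    bold_path: str | Path,
    brain_mask_path: str | Path,
    gm_mask_path: str | Path,
    wm_mask_path: str | Path,
    tr: float,
    motion_path: str | Path | None = None,
) -> BoldDataset:
    """Assemble a BoldDataset from NIfTI/TSV files, checking geometry."""
    data, affine = read_nifti(bold_path)
    if data.ndim != 4:
        raise ValueError(f"{bold_path} is not a 4-D image")
    masks = {}
    for name, p in (
        ("brain_mask", brain_mask_path),
        ("gm_mask", gm_mask_path),
        ("wm_mask", wm_mask_path),
    ):
        m, m_aff = read_nifti(p)
        if m.shape != data.shape[:3]:
            raise ValueError(f"{name} {p}: shape {m.shape} != {data.shape[:3]}")
        if not np.allclose(m_aff, affine, atol=1e-4):
            raise ValueError(f"{name} {p}: affine differs from the BOLD image")
        masks[name] = m > 0.5
    motion = read_motion(motion_path) if motion_path is not None else None
    return BoldDataset(data=data, tr=tr, motion6=motion, affine=affine, **masks)


@dataclass
class SimulateConfig:
    """Configuration of the synthetic bundle; ``seed`` is mandatory."""

    seed: int | None = None
    shape: tuple[int, int, int] = (20, 20, 10)
    tr: float = 1.26
    n_trials: int = 4
    hold: float = 15.0
    baseline: float = 30.0
    lead_in: float = 59.0
    breathing_rate: float = 0.25
    baseline_petco2: float = 38.0
    delta_petco2: float = 8.0
    capno_noise_sd: float = 0.5
    gm_cvr: float = 0.45
    wm_cvr: float = 0.20
    gm_lag: float = -0.2
    wm_lag: float = 0.2
    lag_sd: float = 1.0
    lag_range: tuple[float, float] = (-3.0, 3.0)
    lag_grid: float | None = None
    noise_sd: float = 0.01
    drift_amp: float = 0.005
    motion_amp: float = 0.002
    hrf_delay: float = 6.0
    hrf_shape: str = "single"
    convolve_truth: bool = True

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError(
                "SimulateConfig.seed must be set: simulation is stochastic"
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulateConfig":
        with open(path) as fh:
            raw = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("shape", "lag_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def simulate_dataset(cfg: SimulateConfig):
    """Generate the full synthetic bundle in memory.

    Returns (BoldDataset, GroundTruth, SimulatedCapnograph, BHParadigm).
    The BOLD truth regressor is the ideal end-tidal course, optionally
    convolved with the configured HRF.
    """
    from . import hrf as hrf_mod
    from .simulate import (
        make_ground_truth,
        simulate_bold,
        simulate_capnograph,
        simulate_motion,
    )
    from .design import convolve

    cfg.validate()
    paradigm = make_paradigm(
        cfg.n_trials,
        cfg.hold,
        cfg.baseline,
        cfg.lead_in,
        breathing_rate=cfg.breathing_rate,
    )
    capno = simulate_capnograph(
        paradigm,
        baseline_petco2=cfg.baseline_petco2,
        delta=cfg.delta_petco2,
        noise_sd=cfg.capno_noise_sd,
        seed=cfg.seed,
    )
    truth = make_ground_truth(
        cfg.shape,
        gm_cvr=cfg.gm_cvr,
        wm_cvr=cfg.wm_cvr,
        gm_lag=cfg.gm_lag,
        wm_lag=cfg.wm_lag,
        lag_sd=cfg.lag_sd,
        lag_range=cfg.lag_range,
        lag_grid=cfg.lag_grid,
        delta_petco2=cfg.delta_petco2,
        seed=cfg.seed + 1,
    )
    source = capno.ideal_petco2()
    if cfg.convolve_truth:
        kernel = hrf_mod.sample_kernel(
            hrf_mod.make_params(cfg.hrf_delay, cfg.hrf_shape)
        )
        source = convolve(source, kernel)
    n_vols = paradigm.n_volumes(cfg.tr)
    motion = simulate_motion(n_vols, seed=cfg.seed + 2)
    bold = simulate_bold(
        paradigm,
        truth,
        source,
        tr=cfg.tr,
        noise_sd=cfg.noise_sd,
        drift_amp=cfg.drift_amp,
        motion=motion,
        motion_amp=cfg.motion_amp,
        seed=cfg.seed + 3,
    )
    return bold, truth, capno, paradigm


def write_simulation(out_dir: str | Path, cfg: SimulateConfig) -> dict[str, Path]:
    """Simulate and write the full bundle; returns the path map.

    Files: BOLD + masks + ground-truth volumes as NIfTI, events/physio/motion
    TSV, and a JSON with the seed and parameters.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bold, truth, capno, paradigm = simulate_dataset(cfg)
    paths = {
        "bold": write_nifti(out / "bold.nii", bold.data, bold.affine),
        "brain_mask": write_nifti(out / "brain_mask.nii", bold.brain_mask, bold.affine),
        "gm_mask": write_nifti(out / "gm_mask.nii", bold.gm_mask, bold.affine),
        "wm_mask": write_nifti(out / "wm_mask.nii", bold.wm_mask, bold.affine),
        "cvr_true": write_nifti(out / "cvr_true.nii", truth.cvr_true, bold.affine),
        "lag_true": write_nifti(out / "lag_true.nii", truth.lag_true, bold.affine),
        "events": write_events(out / "events.tsv", paradigm),
        "physio": write_physio(out / "physio.tsv", capno.trace),
        "motion": write_motion(out / "motion.tsv", bold.motion6),
    }
    meta = dataclasses.asdict(cfg)
    meta["delta_petco2_true"] = truth.delta_petco2_true
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=list)
    paths["meta"] = out / "ground_truth.json"
    return paths
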