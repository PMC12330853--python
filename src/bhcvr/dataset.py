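"""In-memory container for a 4-D BOLD run plus its masks and motion table."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["BoldDataset"]


@dataclass
class BoldDataset:
    """A 4-D BOLD time series in scanner units.

    ``data`` is (x, y, z, t).  Masks are binary 3-D arrays aligned with the
    spatial grid; ``motion6`` holds one row of rigid-body parameters per
    volume (3 translations, 3 rotations).  ``affine`` carries voxel geometry.
    """

    data: np.ndarray
    tr: float
    brain_mask: np.ndarray
    gm_mask: np.ndarray
    wm_mask: np.ndarray
    motion6: np.ndarray | None = None
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D (x, y, z, t)")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.data.shape[3] < 2:
            raise ValueError("need at least 2 volumes")
        shape = self.data.shape[:3]
        for name in ("brain_mask", "gm_mask", "wm_mask"):
            mask = np.asarray(getattr(self, name)).astype(bool)
            if mask.shape != shape:
                raise ValueError(f"{name} shape {mask.shape} != data {shape}")
            setattr(self, name, mask)
        if self.motion6 is not None:
            m = np.asarray(self.motion6, dtype=float)
            if m.ndim != 2 or m.shape[1] != 6:
                raise ValueError("motion6 must have 6 columns")
            if m.shape[0] != self.n_volumes:
                raise ValueError("motion6 rows must match number of volumes")
            self.motion6 = m
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def frame_times(self) -> np.ndarray:
        """Acquisition time of each volume: k * TR (no slice-timing offsets)."""
        return np.arange(self.n_volumes) * self.tr

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Voxel edge lengths in mm, from the affine."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def with_data(self, data: np.ndarray) -> "BoldDataset":
        """Copy of this dataset with ``data`` replaced (masks etc. shared)."""
        return replace(self, data=data)
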