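"""In-memory 3-D activity-concentration image.

Voxel values are always Bq/mL — the native quantitative unit of PET — and
the grid is axis-aligned: world position of voxel ``(i, j, k)`` is
``origin + (i, j, k) * spacing`` with ``z`` (index ``k``) the scanner axis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import datetime

import numpy as np

from .errors import MetadataError

__all__ = ["ImageVolume"]


@dataclass
class ImageVolume:
    """A 3-D activity-concentration grid with spacing, origin and scan metadata."""

    voxels: np.ndarray  # (nx, ny, nz), Bq/mL
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float]
    acquisition_start: datetime
    radionuclide: str
    units: str = "Bq/mL"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise MetadataError(f"expected a 3-D grid, got shape {self.voxels.shape}")
        if not all(s > 0 for s in self.spacing_mm):
            raise MetadataError(f"spacing components must be positive, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.voxels)):
            raise MetadataError("voxel values must be finite")
        if self.units != "Bq/mL":
            raise MetadataError(f"only Bq/mL volumes are supported, got {self.units!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def affine(self) -> np.ndarray:
        """4×4 voxel-index → world (mm) affine (diagonal, axis-aligned)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing_mm)
        aff[:3, 3] = self.origin_mm
        return aff

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis."""
        n = self.voxels.shape[axis]
        return self.origin_mm[axis] + self.spacing_mm[axis] * np.arange(n)

    @property
    def voxel_volume_ml(self) -> float:
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz / 1000.0

    def with_voxels(self, voxels: np.ndarray) -> "ImageVolume":
        """Copy of this volume with new voxel data and identical metadata."""
        return replace(self, voxels=np.asarray(voxels, dtype=np.float64))

    def world_extent(self) -> tuple[np.ndarray, np.ndarray]:
        """(min, max) world coordinates of the grid's outer voxel faces."""
        lo = np.asarray(self.origin_mm) - 0.5 * np.asarray(self.spacing_mm)
        hi = lo + np.asarray(self.spacing_mm) * np.asarray(self.voxels.shape)
        return lo, hi
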