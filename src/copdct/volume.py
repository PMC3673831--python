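"""CT volume container and file I/O.

A :class:`CTVolume` is a 3D scalar grid of Hounsfield Units (HU) with
millimetre voxel spacing and a respiratory phase tag.  Axis order is
``(x, y, z)`` with 0-based voxel indices; the world coordinate of voxel
``(i, j, k)`` is ``(i, j, k) * spacing`` in mm (no origin/direction handling —
phantom volumes share one grid, so no registration problem arises).

Volumes are read and written through SimpleITK, so any format it supports
works (``.nii.gz``, ``.mha``, ...).  Masks are 8-bit label volumes on the
same grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .errors import ConfigurationError

VALID_PHASES = ("inspiratory", "expiratory")


@dataclass
class CTVolume:
    """3D HU voxel grid with mm spacing and respiratory phase."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    phase: str = "inspiratory"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise ConfigurationError("voxels: expected a 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ConfigurationError("spacing: must be three positive mm values")
        if self.phase not in VALID_PHASES:
            raise ConfigurationError(f"phase: must be one of {VALID_PHASES}")
        if not np.all(np.isfinite(self.voxels)):
            raise ConfigurationError("voxels: HU values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def world_to_index(self, point_mm) -> np.ndarray:
        """Continuous (fractional) voxel index of a world-mm point."""
        return np.asarray(point_mm, dtype=float) / np.asarray(self.spacing)

    def index_to_world(self, index) -> np.ndarray:
        return np.asarray(index, dtype=float) * np.asarray(self.spacing)

    def contains_world(self, point_mm) -> bool:
        idx = self.world_to_index(point_mm)
        return bool(np.all(idx >= 0) and np.all(idx <= np.asarray(self.shape) - 1))


def write_volume(vol: CTVolume, path: str | Path) -> None:
    """Write a volume to any SimpleITK-supported format (.nii.gz, .mha, ...)."""
    # SimpleITK is z-fastest-last: transpose (x,y,z) -> (z,y,x)
    img = sitk.GetImageFromArray(np.transpose(vol.voxels, (2, 1, 0)))
    img.SetSpacing(vol.spacing)
    sitk.WriteImage(sitk.Cast(img, sitk.sitkFloat32), str(path))


def read_volume(path: str | Path, phase: str = "inspiratory") -> CTVolume:
    img = sitk.ReadImage(str(path))
    arr = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0)).astype(np.float32)
    return CTVolume(arr, tuple(img.GetSpacing()), phase)


def write_mask(mask: np.ndarray, spacing, path: str | Path) -> None:
    img = sitk.GetImageFromArray(np.transpose(mask.astype(np.uint8), (2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in spacing))
    sitk.WriteImage(img, str(path))


def read_mask(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = sitk.ReadImage(str(path))
    arr = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    return arr.astype(bool), tuple(img.GetSpacing())
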