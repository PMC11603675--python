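"""HU-valued voxel volumes and NRRD input/output.

The in-memory convention throughout the package is array index order
``(ix, iy, iz)`` with world position ``origin + index * spacing`` in mm,
so axis 0 of the array is the anatomical X axis.  SimpleITK stores arrays
as ``(z, y, x)``; the transpose happens at the I/O boundary only.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

__all__ = ["VoxelVolume", "BinaryMask", "read_volume", "write_volume"]


@dataclass
class VoxelVolume:
    """A 3D scalar grid in Hounsfield units.

    Parameters
    ----------
    values : (nx, ny, nz) float array
        Grey values in HU.
    spacing : (3,) float array
        Voxel edge lengths in mm, all positive.
    origin : (3,) float array
        World coordinate of the center of voxel (0, 0, 0), in mm.
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("volume values must be a non-empty 3D array")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be three positive lengths (mm)")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def voxel_volume_mm3(self) -> float:
        """Volume of a single voxel in mm³."""
        return float(np.prod(self.spacing))


@dataclass
class BinaryMask:
    """Boolean voxel mask sharing the grid of its source volume."""

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("mask must be a 3D array")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def count(self) -> int:
        return int(self.values.sum())


def read_volume(path: str) -> VoxelVolume:
    """Read a scalar volume (NRRD or any SimpleITK-supported format).

    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` for a
    file SimpleITK cannot parse.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        img = sitk.ReadImage(path)
    except RuntimeError as exc:  # malformed header
        raise ValueError(f"could not read volume {path!r}: {exc}") from exc
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    values = np.transpose(arr, (2, 1, 0))
    spacing = np.asarray(img.GetSpacing(), dtype=float)  # already (x, y, z)
    origin = np.asarray(img.GetOrigin(), dtype=float)
    return VoxelVolume(values=values, spacing=spacing, origin=origin)


def write_volume(volume: VoxelVolume, path: str) -> None:
    """Write a volume; format chosen by extension (use .nrrd)."""
    img = sitk.GetImageFromArray(np.transpose(volume.values, (2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in volume.spacing))
    img.SetOrigin(tuple(float(o) for o in volume.origin))
    sitk.WriteImage(img, path)
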