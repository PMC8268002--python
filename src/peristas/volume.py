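"""Spatial containers: CT volumes and binary voxel masks with mm geometry.

Both types carry per-axis voxel spacing in millimeters and a NIfTI-style
affine so that masks produced by morphology can be written next to the
image they were derived from.  All morphology downstream is spacing-aware;
nothing in the package assumes isotropic voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np


def _default_affine(spacing_mm: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


@dataclass
class CtVolume:
    """A 3D scalar CT grid in Hounsfield units plus its geometry."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"voxel spacing must be strictly positive, got {self.spacing_mm}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def same_geometry(self, other: "CtVolume | VoxelMask") -> bool:
        return (
            self.data.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.affine, other.affine)
        )

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.float32), self.affine)

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "CtVolume":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asanyarray(img.dataobj).astype(np.float64), spacing, np.asarray(img.affine))


@dataclass
class VoxelMask:
    """A boolean 3D grid sharing a CtVolume's geometry."""

    grid: np.ndarray
    spacing_mm: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid).astype(bool)
        if self.grid.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={self.grid.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"voxel spacing must be strictly positive, got {self.spacing_mm}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def voxel_count(self) -> int:
        return int(self.grid.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def volume_mm3(self) -> float:
        return self.voxel_count * self.voxel_volume_mm3

    def is_empty(self) -> bool:
        return not self.grid.any()

    def same_geometry(self, other: "CtVolume | VoxelMask") -> bool:
        oshape = other.shape
        return (
            self.grid.shape == oshape
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.affine, other.affine)
        )

    def is_subset_of(self, other: "VoxelMask") -> bool:
        return bool(np.all(~self.grid | other.grid))

    def with_grid(self, grid: np.ndarray) -> "VoxelMask":
        """A new mask with the same geometry but different voxels."""
        return VoxelMask(grid, self.spacing_mm, self.affine)

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.grid.astype(np.uint8), self.affine)

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "VoxelMask":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asanyarray(img.dataobj) > 0, spacing, np.asarray(img.affine))
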