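"""Millimeter-accurate morphology: perinodular shells and the interface band.

Dilation and erosion are realized by thresholding an exact Euclidean
distance transform (spacing-aware), not by iterated structuring elements,
so a "2 mm" shell is 2 mm thick on anisotropic grids too.  Distances are
measured voxel-center to voxel-center and boundary voxels at exactly the
requested distance are included (<=).

The eight VOIs per case are the tumor core, the cumulative perinodular
shells at 2/4/6/8/10/20 mm from the tumor surface (each clipped to the
lung mask and excluding the core), and the tumor-lung interface band
spanning 3 mm inside plus 3 mm outside the tumor contour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import VoxelMask

#: Cumulative perinodular shell distances (mm), from the tumor surface.
SHELL_DISTANCES_MM: tuple[float, ...] = (2, 4, 6, 8, 10, 20)

#: Fixed VOI ordering used for feature concatenation.
VOI_ORDER: tuple[str, ...] = (
    "core",
    "shell_2mm",
    "shell_4mm",
    "shell_6mm",
    "shell_8mm",
    "shell_10mm",
    "shell_20mm",
    "tumor_lung",
)


def distance_from_mask_mm(mask: VoxelMask) -> np.ndarray:
    """Exact Euclidean distance (mm) of every voxel to the nearest mask voxel.

    Zero inside the mask.  Empty mask -> +inf everywhere.
    """
    if mask.is_empty():
        return np.full(mask.shape, np.inf)
    return ndimage.distance_transform_edt(~mask.grid, sampling=mask.spacing_mm)


def distance_from_background_mm(mask: VoxelMask) -> np.ndarray:
    """Distance (mm) of every mask voxel to the nearest non-mask voxel.

    Voxels outside the mask have distance 0.  Voxels of an all-true mask
    are treated as infinitely deep.
    """
    if mask.grid.all():
        return np.where(mask.grid, np.inf, 0.0)
    return ndimage.distance_transform_edt(mask.grid, sampling=mask.spacing_mm)


def dilate_mm(mask: VoxelMask, d: float) -> VoxelMask:
    """Dilate by a physical distance: voxels within ``d`` mm of the mask."""
    if d < 0:
        raise ValueError(f"dilation distance must be >= 0, got {d}")
    if d == 0 or mask.is_empty():
        return mask.with_grid(mask.grid.copy())
    dist = distance_from_mask_mm(mask)
    return mask.with_grid((dist <= d) | mask.grid)


def erode_mm(mask: VoxelMask, d: float) -> VoxelMask:
    """Erode by a physical distance: voxels deeper than ``d`` mm inside."""
    if d < 0:
        raise ValueError(f"erosion distance must be >= 0, got {d}")
    if d == 0 or mask.is_empty():
        return mask.with_grid(mask.grid.copy())
    dist = distance_from_background_mm(mask)
    return mask.with_grid(dist > d)


def _check_core_lung(core: VoxelMask, lung: VoxelMask) -> None:
    if core.is_empty():
        raise ValueError("core mask is empty")
    if not core.same_geometry(lung):
        raise ValueError("core and lung masks do not share geometry")
    if not core.is_subset_of(lung):
        n_out = int((core.grid & ~lung.grid).sum())
        raise ValueError(f"core mask extends outside the lung mask ({n_out} voxels)")


def perinodular_shell(core: VoxelMask, lung: VoxelMask, d: float) -> VoxelMask:
    """Cumulative perinodular shell: lung tissue within ``d`` mm of the tumor.

    (dilate(core, d) & lung) - core.  Clipping to the lung mask is the
    extrapulmonary-exclusion guarantee: shells of pleurally-attached
    nodules never reach outside the lung.
    """
    if d <= 0:
        raise ValueError(f"shell distance must be > 0, got {d}")
    _check_core_lung(core, lung)
    grown = dilate_mm(core, d)
    return core.with_grid(grown.grid & lung.grid & ~core.grid)


def interface_band(core: VoxelMask, lung: VoxelMask, r: float = 3.0) -> VoxelMask:
    """Tumor-lung interface band: ``r`` mm inside plus ``r`` mm outside the contour.

    (dilate(core, r) & lung) - erode(core, r).  For tumors thinner than
    ``r`` the erosion is empty and the band covers the whole core.
    """
    if r <= 0:
        raise ValueError(f"band half-width must be > 0, got {r}")
    _check_core_lung(core, lung)
    outer = dilate_mm(core, r)
    inner = erode_mm(core, r)
    return core.with_grid(outer.grid & lung.grid & ~inner.grid)


def annular_ring(core: VoxelMask, lung: VoxelMask, d_in: float, d_out: float) -> VoxelMask:
    """Annular perinodular ring between two surface distances (utility).

    The primary VOIs are cumulative; rings are their set differences.
    """
    if not 0 <= d_in < d_out:
        raise ValueError(f"need 0 <= d_in < d_out, got ({d_in}, {d_out})")
    outer = perinodular_shell(core, lung, d_out)
    if d_in == 0:
        return outer
    inner = perinodular_shell(core, lung, d_in)
    return core.with_grid(outer.grid & ~inner.grid)


@dataclass
class VoiSet:
    """The eight VOIs of one case, in the fixed concatenation order."""

    core: VoxelMask
    shells: dict[float, VoxelMask]
    interface: VoxelMask
    band_mm: float = 3.0

    def __post_init__(self) -> None:
        if tuple(sorted(self.shells)) != tuple(sorted(SHELL_DISTANCES_MM)) and len(self.shells) == 0:
            raise ValueError("shells mapping is empty")

    @property
    def distances(self) -> tuple[float, ...]:
        return tuple(sorted(self.shells))

    def members(self) -> dict[str, VoxelMask]:
        """All VOIs keyed by canonical name, in concatenation order."""
        out: dict[str, VoxelMask] = {"core": self.core}
        for d in sorted(self.shells):
            out[f"shell_{d:g}mm"] = self.shells[d]
        out["tumor_lung"] = self.interface
        return out

    def voxel_counts(self) -> dict[str, int]:
        return {name: m.voxel_count for name, m in self.members().items()}

    def volumes_mm3(self) -> dict[str, float]:
        return {name: m.volume_mm3 for name, m in self.members().items()}


def build_voi_set(
    core: VoxelMask,
    lung: VoxelMask,
    distances: tuple[float, ...] = SHELL_DISTANCES_MM,
    band_mm: float = 3.0,
) -> VoiSet:
    """Construct the full VOI set for a case.

    A single distance map from the core serves all cumulative shells, so the
    nesting VOI_2mm <= VOI_4mm <= ... <= VOI_20mm holds by construction.
    Empty shells (core filling the lung) are kept with a warning.
    """
    _check_core_lung(core, lung)
    if lung.is_empty():
        raise ValueError("lung mask is empty")
    dist = distance_from_mask_mm(core)
    shells: dict[float, VoxelMask] = {}
    for d in distances:
        if d <= 0:
            raise ValueError(f"shell distance must be > 0, got {d}")
        grid = (dist <= d) & lung.grid & ~core.grid
        if not grid.any():
            warnings.warn(f"perinodular shell at {d} mm is empty", stacklevel=2)
        shells[float(d)] = core.with_grid(grid)
    inner = erode_mm(core, band_mm)
    band = core.with_grid((dist <= band_mm) & lung.grid & ~inner.grid | (core.grid & ~inner.grid))
    return VoiSet(core=core.with_grid(core.grid.copy()), shells=shells, interface=band, band_mm=band_mm)
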