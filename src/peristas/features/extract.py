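"""Assembly of per-VOI (851) and per-case (6,808) feature vectors.

Feature names encode VOI x image filter x family x feature as
``voi__filter__family__feature`` (e.g. ``core__wavelet-HHL__glcm__Contrast``);
the order is fixed: shape first, then for the original image and each of
the 8 wavelet bands the 18 first-order + 24 GLCM + 16 GLRLM + 16 GLSZM +
14 GLDM + 5 NGTDM features.  14 + 9 x 93 = 851 per VOI; the case vector
concatenates the 8 VOIs (core, 2, 4, 6, 8, 10, 20 mm, tumor-lung):
8 x 851 = 6,808.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..shells import VoiSet
from ..volume import CtVolume, VoxelMask
from .discretize import DiscretizationConfig, discretize
from .firstorder import FIRST_ORDER_NAMES, first_order_features
from .shape import SHAPE_NAMES, shape_features
from .texture import FAMILY_FEATURE_NAMES, TEXTURE_FAMILIES, texture_features, texture_matrix
from .wavelet import WAVELET_BAND_NAMES, wavelet_bands

FILTERS: tuple[str, ...] = ("original",) + tuple(f"wavelet-{b}" for b in WAVELET_BAND_NAMES)

N_FEATURES_PER_VOI = len(SHAPE_NAMES) + len(FILTERS) * (
    len(FIRST_ORDER_NAMES) + sum(len(FAMILY_FEATURE_NAMES[f]) for f in TEXTURE_FAMILIES)
)
N_FEATURES_PER_CASE = 8 * N_FEATURES_PER_VOI

#: Value marking the block of a VOI that could not be extracted (empty shell).
MISSING_VALUE = np.nan


@dataclass
class FeatureVector:
    """Named, ordered feature values of one VOI or one whole case."""

    names: list[str]
    values: np.ndarray
    voi_id: str
    missing_vois: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if len(self.names) != len(self.values):
            raise ValueError("names and values length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names are not unique")

    def __len__(self) -> int:
        return len(self.names)

    def to_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


def feature_names_single_voi(voi_id: str) -> list[str]:
    """The fixed 851-name ordering for one VOI."""
    names = [f"{voi_id}__original__shape__{n}" for n in SHAPE_NAMES]
    for filt in FILTERS:
        names += [f"{voi_id}__{filt}__firstorder__{n}" for n in FIRST_ORDER_NAMES]
        for fam in TEXTURE_FAMILIES:
            names += [f"{voi_id}__{filt}__{fam}__{n}" for n in FAMILY_FEATURE_NAMES[fam]]
    return names


def _bbox_slices(mask: np.ndarray, pad: int = 1) -> tuple[slice, ...]:
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad + 1, mask.shape)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def _intensity_block(
    data: np.ndarray,
    mask: np.ndarray,
    voxel_volume: float,
    cfg: DiscretizationConfig,
) -> list[float]:
    """93 first-order + texture values of one filter volume on one VOI."""
    values = list(first_order_features(data, mask, voxel_volume, cfg).values())
    levels, n_levels = discretize(data, mask, cfg)
    for fam in TEXTURE_FAMILIES:
        tm = texture_matrix(levels, n_levels, fam)
        values += list(texture_features(tm).values())
    return values


def _extract_single(
    image_data: np.ndarray,
    bands: dict[str, np.ndarray],
    mask: VoxelMask,
    cfg: DiscretizationConfig,
    voi_id: str,
) -> FeatureVector:
    grid = mask.grid
    if grid.sum() < 2:
        raise ValueError(f"VOI {voi_id!r} has fewer than 2 voxels; texture undefined")
    box = _bbox_slices(grid)
    m = grid[box]
    vv = mask.voxel_volume_mm3

    values = list(shape_features(grid, mask.spacing_mm).values())
    values += _intensity_block(image_data[box], m, vv, cfg)
    for bname in WAVELET_BAND_NAMES:
        values += _intensity_block(bands[bname][box], m, vv, cfg)
    return FeatureVector(names=feature_names_single_voi(voi_id), values=np.array(values), voi_id=voi_id)


def extract_feature_vector(
    image: CtVolume,
    mask: VoxelMask,
    cfg: DiscretizationConfig | None = None,
    voi_id: str = "voi",
    wavelet: str = "coif1",
) -> FeatureVector:
    """The full 851-feature vector of one VOI.  Deterministic."""
    if not image.same_geometry(mask):
        raise ValueError("image and mask must share geometry")
    cfg = cfg or DiscretizationConfig()
    bands = wavelet_bands(image.data, wavelet)
    return _extract_single(image.data, bands, mask, cfg, voi_id)


def extract_multi_voi_firstorder(
    image: CtVolume,
    vois: VoiSet,
    cfg: DiscretizationConfig | None = None,
) -> FeatureVector:
    """First-order-only case vector (18 features x 8 VOIs, original image).

    A lightweight alternative to the full 6,808-column extractor for
    cohort-scale simulation studies where only intensity statistics are
    needed; names follow the same ``voi__filter__family__feature`` scheme,
    so feature-group selection works unchanged.
    """
    cfg = cfg or DiscretizationConfig()
    names: list[str] = []
    values: list[float] = []
    missing: list[str] = []
    for voi_id, mask in vois.members().items():
        block = [f"{voi_id}__original__firstorder__{n}" for n in FIRST_ORDER_NAMES]
        names += block
        if mask.voxel_count < 2:
            missing.append(voi_id)
            values += [MISSING_VALUE] * len(block)
            continue
        box = _bbox_slices(mask.grid)
        vals = first_order_features(
            image.data[box], mask.grid[box], mask.voxel_volume_mm3, cfg
        )
        values += list(vals.values())
    return FeatureVector(names=names, values=np.array(values), voi_id="case", missing_vois=missing)


def extract_multi_voi(
    image: CtVolume,
    vois: VoiSet,
    cfg: DiscretizationConfig | None = None,
    wavelet: str = "coif1",
) -> FeatureVector:
    """The 6,808-feature case vector over the 8 VOIs, in fixed order.

    A VOI with fewer than 2 voxels (an empty shell) contributes a block of
    missing-value sentinels and is listed in ``missing_vois``; such cases
    are meant to be excluded downstream with a logged reason.
    """
    cfg = cfg or DiscretizationConfig()
    bands = wavelet_bands(image.data, wavelet)
    names: list[str] = []
    values: list[float] = []
    missing: list[str] = []
    for voi_id, mask in vois.members().items():
        block_names = feature_names_single_voi(voi_id)
        if mask.voxel_count < 2:
            missing.append(voi_id)
            names += block_names
            values += [MISSING_VALUE] * len(block_names)
            continue
        fv = _extract_single(image.data, bands, mask, cfg, voi_id)
        names += fv.names
        values += fv.values.tolist()
    return FeatureVector(names=names, values=np.array(values), voi_id="case", missing_vois=missing)
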