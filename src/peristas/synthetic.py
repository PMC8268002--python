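"""Synthetic CT phantom cohorts with a planted perinodular STAS signal.

The generator emulates the cohort structure that peritumoral radiomics of
lung adenocarcinoma assumes: ~1 mm near-isotropic chest-CT-like volumes in
Hounsfield units, lung parenchyma around -800 HU, part-solid nodules with a
consolidation-to-tumor ratio (CTR) controlling the solid-core fraction,
nodules placed both centrally and against the pleural boundary, and a class
imbalance of roughly 56 STAS-positive to 160 STAS-negative cases.

The STAS-positive signal is perinodular *only*: a Gaussian-blurred rim
(interface blurring), extra textural heterogeneity, and Poisson-scattered
1-3 mm hyperdense satellite micro-clusters, all confined to within 10 mm of
the tumor surface.  Inside the nodule the two classes are drawn from the
same distribution, so a core-only model is handicapped by construction —
the property the intra+perinodular analysis is designed to demonstrate.

The lung field is two ellipsoids inside a soft-tissue body; only the mask
boundary matters downstream (pleural clipping of shells), so no airway tree
or vasculature is modeled.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volume import CtVolume, VoxelMask

#: Cohort sizes mirroring the 56 STAS+ / 160 STAS- study population.
DEFAULT_N_POS = 56
DEFAULT_N_NEG = 160

#: Mean +/- SD of nodule mean diameter (mm) and of CTR in the emulated cohort.
DIAMETER_MEAN_SD_MM = (19.7, 6.2)
CTR_MEAN_SD = (0.7, 0.3)

SOLID_HU_RANGE = (0.0, 60.0)
GROUND_GLASS_HU_RANGE = (-600.0, -300.0)
BODY_HU = 40.0

STAS_SIGNAL_REACH_MM = 10.0  # planted signal lives within this distance of the surface


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic case / cohort.

    peritumoral_effect is the effect-size scalar (>= 0) of the planted
    STAS-positive signal: it scales satellite density, interface blur
    width, and the extra perinodular heterogeneity.  0 means STAS+ cases
    are statistically identical to STAS- outside the core.
    """

    grid_shape: tuple[int, int, int] = (80, 80, 80)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lung_hu: float = -800.0
    noise_sd: float = 25.0
    nodule_diameter_mm: float = DIAMETER_MEAN_SD_MM[0]
    diameter_sd_mm: float = DIAMETER_MEAN_SD_MM[1]
    ctr: float = CTR_MEAN_SD[0]
    ctr_sd: float = CTR_MEAN_SD[1]
    peritumoral_effect: float = 1.0
    pleural_contact_prob: float = 0.3
    margin_mm: float = 20.0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be strictly positive on all axes")
        if not 0.0 <= self.ctr <= 1.0:
            raise ValueError(f"ctr must be in [0, 1], got {self.ctr}")
        if self.peritumoral_effect < 0:
            raise ValueError("peritumoral_effect must be >= 0")
        if self.nodule_diameter_mm <= 0:
            raise ValueError("nodule_diameter_mm must be > 0")

    def max_fitting_diameter_mm(self) -> float:
        """Largest nodule diameter the grid can hold with the required margin."""
        extents = [n * s for n, s in zip(self.grid_shape, self.spacing_mm)]
        return min(extents) - 2 * self.margin_mm

    def validate_fit(self, diameter_mm: float) -> None:
        limit = self.max_fitting_diameter_mm()
        if diameter_mm > limit:
            raise ValueError(
                f"nodule of {diameter_mm:.1f} mm cannot fit in the grid with a "
                f"{self.margin_mm:.0f} mm margin (max {limit:.1f} mm)"
            )


@dataclass
class LabeledCase:
    """One synthetic patient record: image + lung mask + tumor mask + label."""

    image: CtVolume
    lung: VoxelMask
    core: VoxelMask
    label: int  # 1 = STAS positive, 0 = STAS negative
    seed: int
    diameter_mm: float = float("nan")
    ctr: float = float("nan")

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        if not self.image.same_geometry(self.lung) or not self.image.same_geometry(self.core):
            raise ValueError("image, lung and core must share geometry")
        if self.core.is_empty():
            raise ValueError("core mask is empty")
        if not self.core.is_subset_of(self.lung):
            raise ValueError("core mask must be a subset of the lung mask")

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.image.save(out / "image.nii.gz")
        self.lung.save(out / "lung.nii.gz")
        self.core.save(out / "tumor.nii.gz")


def case_seed(master_seed: int, index: int) -> int:
    """Reproducible per-case seed derived by hashing (master, index)."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(index),))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _coord_grids_mm(spec: PhantomSpec) -> list[np.ndarray]:
    axes = [np.arange(n) * s for n, s in zip(spec.grid_shape, spec.spacing_mm)]
    return list(np.meshgrid(*axes, indexing="ij"))


_LUNG_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _lung_field_cached(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Lung mask and its interior distance map; deterministic per spec."""
    key = (spec.grid_shape, spec.spacing_mm)
    if key not in _LUNG_CACHE:
        lung = _lung_field(spec)
        dist_in = ndimage.distance_transform_edt(lung, sampling=spec.spacing_mm)
        _LUNG_CACHE[key] = (lung, dist_in)
        if len(_LUNG_CACHE) > 8:
            _LUNG_CACHE.pop(next(iter(_LUNG_CACHE)))
    lung, dist_in = _LUNG_CACHE[key]
    return lung, dist_in


def _lung_field(spec: PhantomSpec) -> np.ndarray:
    """Two lung ellipsoids inside the body; boolean grid."""
    X, Y, Z = _coord_grids_mm(spec)
    ex, ey, ez = (n * s for n, s in zip(spec.grid_shape, spec.spacing_mm))
    lung = np.zeros(spec.grid_shape, dtype=bool)
    # Left/right lungs: centers offset along x, semi-axes chosen to leave a
    # mediastinal gap and a soft-tissue border on all sides.
    for cx_frac in (0.27, 0.73):
        cx, cy, cz = cx_frac * ex, 0.5 * ey, 0.5 * ez
        ax, ay, az = 0.20 * ex, 0.40 * ey, 0.44 * ez
        lung |= ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2 <= 1.0
    return lung


def _nodule_mask(
    spec: PhantomSpec,
    rng: np.random.Generator,
    lung: np.ndarray,
    dist_in: np.ndarray,
    diameter_mm: float,
    pleural: bool,
) -> np.ndarray:
    """An ellipsoidal nodule inside one lung, optionally hugging the pleura."""
    X, Y, Z = _coord_grids_mm(spec)
    # mild random anisotropy around the target mean diameter
    ratios = rng.uniform(0.85, 1.15, size=3)
    ratios *= diameter_mm / 2 / np.cbrt(np.prod(ratios))
    ax, ay, az = ratios

    r_eff = max(ax, ay, az)
    if pleural:
        # center 40-80% of the radius inside the boundary -> nodule pokes out
        depth_lo, depth_hi = 0.4 * r_eff, 0.8 * r_eff
    else:
        depth_lo, depth_hi = r_eff, np.inf
    candidates = np.argwhere((dist_in >= depth_lo) & (dist_in <= depth_hi))
    if len(candidates) == 0:  # lung too small for a fully interior seat
        candidates = np.argwhere(dist_in == dist_in.max())
    center_idx = candidates[rng.integers(len(candidates))]
    cx, cy, cz = (i * s for i, s in zip(center_idx, spec.spacing_mm))
    nod = ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2 <= 1.0
    return nod & lung


def generate_case(spec: PhantomSpec, label: int, seed: int) -> LabeledCase:
    """Generate one labeled phantom; deterministic given (spec, label, seed).

    For ``label=1`` the voxels within 10 mm of the tumor surface carry the
    planted perinodular signal (blurred rim, heterogeneity, satellites)
    scaled by ``spec.peritumoral_effect``; for ``label=0`` the peritumoral
    field is parenchyma plus noise.  The nodule itself (size, CTR,
    intensities) is drawn identically for both classes.
    """
    if label not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {label}")
    rng = np.random.default_rng(seed)

    spec.validate_fit(spec.nodule_diameter_mm)
    # cohort diameters: truncated normal over the realistic 10-50 mm range,
    # further truncated to what the grid can hold with its margin
    hi = min(50.0, spec.max_fitting_diameter_mm())
    diameter = float(np.clip(rng.normal(spec.nodule_diameter_mm, spec.diameter_sd_mm), min(10.0, hi), hi))
    ctr = float(np.clip(rng.normal(spec.ctr, spec.ctr_sd), 0.0, 1.0))
    pleural = bool(rng.uniform() < spec.pleural_contact_prob)

    lung, lung_dist_in = _lung_field_cached(spec)
    nodule = _nodule_mask(spec, rng, lung, lung_dist_in, diameter, pleural)

    # ---- intensity model -------------------------------------------------
    img = np.full(spec.grid_shape, BODY_HU, dtype=np.float64)
    img[lung] = spec.lung_hu

    # per-case work happens on a bounding box around the nodule plus the
    # signal reach; everything outside it is untouched parenchyma
    pad_vox = [int(np.ceil((STAS_SIGNAL_REACH_MM + 5.0) / s)) for s in spec.spacing_mm]
    idx = np.argwhere(nodule)
    lo = np.maximum(idx.min(axis=0) - pad_vox, 0)
    hi = np.minimum(idx.max(axis=0) + pad_vox + 1, spec.grid_shape)
    box = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    nod_b, lung_b = nodule[box], lung[box]

    solid_hu = rng.uniform(*SOLID_HU_RANGE)
    ggo_hu = rng.uniform(*GROUND_GLASS_HU_RANGE)
    # solid core occupies a CTR fraction of the diameter: keep voxels deeper
    # than (1 - ctr) * max-depth from the nodule surface
    dist_from_edge = ndimage.distance_transform_edt(nod_b, sampling=spec.spacing_mm)
    r_max = dist_from_edge.max()
    solid = dist_from_edge >= (1.0 - ctr) * r_max if ctr > 0 else np.zeros_like(nod_b)
    img_b = img[box]
    img_b[nod_b] = ggo_hu
    img_b[solid] = solid_hu

    # ---- planted STAS-positive perinodular signal ------------------------
    eff = spec.peritumoral_effect
    if label == 1 and eff > 0:
        dist_out = ndimage.distance_transform_edt(~nod_b, sampling=spec.spacing_mm)
        peri = (dist_out > 0) & (dist_out <= STAS_SIGNAL_REACH_MM) & lung_b

        # interface blurring: smooth the image near the tumor edge
        blur_sigma = 1.0 * eff  # mm
        sig_vox = [blur_sigma / s for s in spec.spacing_mm]
        blurred = ndimage.gaussian_filter(img_b, sigma=sig_vox)
        rim = (dist_out > 0) & (dist_out <= 3.0) & lung_b
        img_b[rim] = blurred[rim]

        # elevated textural heterogeneity in the perinodular field
        hetero = ndimage.gaussian_filter(rng.normal(0.0, 1.0, img_b.shape), sigma=1.5)
        hetero /= max(hetero.std(), 1e-12)
        img_b[peri] += 60.0 * eff * hetero[peri]

        # Poisson-scattered 1-3 mm hyperdense satellite micro-clusters
        n_sat = rng.poisson(4.0 * eff)
        peri_idx = np.argwhere(peri)
        bx = [np.arange(b.start, b.stop) * s for b, s in zip(box, spec.spacing_mm)]
        Xb, Yb, Zb = np.meshgrid(*bx, indexing="ij")
        for _ in range(min(n_sat, len(peri_idx))):
            c = peri_idx[rng.integers(len(peri_idx))]
            cx, cy, cz = ((i + b.start) * s for i, b, s in zip(c, box, spec.spacing_mm))
            r_sat = rng.uniform(0.5, 1.5)  # radius -> 1-3 mm diameter
            blob = (Xb - cx) ** 2 + (Yb - cy) ** 2 + (Zb - cz) ** 2 <= r_sat**2
            img_b[blob & peri] = rng.uniform(-150.0, 0.0)

    img[box] = img_b
    img += rng.normal(0.0, spec.noise_sd, spec.grid_shape)

    aff = np.diag([*spec.spacing_mm, 1.0])
    return LabeledCase(
        image=CtVolume(img, spec.spacing_mm, aff),
        lung=VoxelMask(lung, spec.spacing_mm, aff),
        core=VoxelMask(nodule, spec.spacing_mm, aff),
        label=label,
        seed=seed,
        diameter_mm=diameter,
        ctr=ctr,
    )


def generate_cohort(
    n_pos: int,
    n_neg: int,
    spec: PhantomSpec | None = None,
    seed: int = 0,
) -> list[LabeledCase]:
    """Generate a labeled cohort; per-case seeds hashed from the master seed.

    Cases are ordered positives first; case index is the hashing key, so a
    case's content depends only on (spec, label, master seed, index).
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("cohort sizes must be >= 0")
    spec = spec or PhantomSpec()
    labels = [1] * n_pos + [0] * n_neg
    return [generate_case(spec, lab, case_seed(seed, i)) for i, lab in enumerate(labels)]


def write_cohort(cases: list[LabeledCase], out_dir: str | Path) -> Path:
    """Write per-case NIfTI files and the cohort manifest CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case_id", "label", "seed", "diameter_mm", "ctr"])
        for i, case in enumerate(cases):
            cid = f"case_{i:04d}"
            case.save(out / cid)
            writer.writerow([cid, case.label, case.seed, f"{case.diameter_mm:.3f}", f"{case.ctr:.3f}"])
    return manifest
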