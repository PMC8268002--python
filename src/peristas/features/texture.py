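"""Gray-level texture matrices and their scalar features.

Five families on a discretized (integer-level) grid:

* GLCM  — co-occurrence at distance 1 over the 13 unique 3D directions,
  symmetric; the 24 features are computed per direction and averaged.
* GLRLM — run lengths per direction (same 13 directions); 16 features,
  averaged over directions.
* GLSZM — zone sizes with 26-connectivity; 16 features, one matrix.
* GLDM  — dependence counts (alpha = 0, Chebyshev distance 1, so 26
  neighbors); dependence of a voxel = 1 + number of equal-level in-mask
  neighbors; 14 features.
* NGTDM — neighborhood gray-tone difference sums over the 26-neighborhood;
  5 features.

Degenerate inputs (a single gray level) produce defined limit values
(0*log 0 = 0), never NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

TEXTURE_FAMILIES: tuple[str, ...] = ("glcm", "glrlm", "glszm", "gldm", "ngtdm")

#: The 13 unique direction offsets of a 26-neighborhood (one per +/- pair).
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

_OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


@dataclass
class TextureMatrices:
    """One family's matrix stack for one VOI."""

    kind: str
    matrix: np.ndarray  # glcm/glrlm: (13, ...) per direction; else single matrix
    n_levels: int
    n_voxels: int
    aggregation: str = "direction-averaged"

    def __post_init__(self) -> None:
        if self.kind not in TEXTURE_FAMILIES:
            raise ValueError(f"unknown texture family {self.kind!r}")


# --------------------------------------------------------------------------
# matrix construction
# --------------------------------------------------------------------------

def _shifted_views(levels: np.ndarray, off: tuple[int, int, int]):
    """Aligned views (a, b) with b displaced by ``off`` relative to a."""
    sl_a, sl_b = [], []
    for o, n in zip(off, levels.shape):
        if o >= 0:
            sl_a.append(slice(0, n - o))
            sl_b.append(slice(o, n))
        else:
            sl_a.append(slice(-o, n))
            sl_b.append(slice(0, n + o))
    return levels[tuple(sl_a)], levels[tuple(sl_b)]


def glcm_matrices(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Symmetric co-occurrence counts, one (Ng, Ng) matrix per direction."""
    g = n_levels
    out = np.zeros((len(DIRECTIONS_13), g, g), dtype=np.float64)
    for k, off in enumerate(DIRECTIONS_13):
        a, b = _shifted_views(levels, off)
        valid = (a > 0) & (b > 0)
        idx = (a[valid].astype(np.int64) - 1) * g + (b[valid] - 1)
        m = np.bincount(idx, minlength=g * g).reshape(g, g).astype(np.float64)
        out[k] = m + m.T
    return out


def glrlm_matrices(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Run-length counts P[level, length], one matrix per direction.

    Runs are maximal sequences of equal-level in-mask voxels consecutive
    along a direction.  In-mask voxels are ordered by (line id, position
    along the line); run-length encoding of that ordering is exact because
    any out-of-mask gap breaks the position sequence.
    """
    coords = np.argwhere(levels > 0)
    vals = levels[levels > 0].astype(np.int64)
    max_len = int(max(levels.shape))
    out = np.zeros((len(DIRECTIONS_13), n_levels, max_len), dtype=np.float64)
    if len(coords) == 0:
        return out
    for k, off in enumerate(DIRECTIONS_13):
        d = np.asarray(off)
        # position along the line: the coordinate of any moving axis
        axis = int(np.nonzero(d)[0][0])
        t = coords[:, axis] * d[axis]  # strictly increasing along +d
        line = coords - t[:, None] * d[None, :]
        order = np.lexsort((t, line[:, 2], line[:, 1], line[:, 0]))
        tv, lv = t[order], vals[order]
        ln = line[order]
        same_line = np.all(ln[1:] == ln[:-1], axis=1)
        cont = same_line & (tv[1:] == tv[:-1] + 1) & (lv[1:] == lv[:-1])
        # run boundaries
        breaks = np.flatnonzero(~cont)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [len(tv) - 1]))
        run_len = ends - starts + 1
        run_lvl = lv[starts]
        np.add.at(out[k], (run_lvl - 1, run_len - 1), 1.0)
    return out


def glszm_matrix(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Zone-size counts P[level, size] with 26-connected zones."""
    structure = np.ones((3, 3, 3), dtype=int)
    n_vox = int((levels > 0).sum())
    out = np.zeros((n_levels, max(n_vox, 1)), dtype=np.float64)
    for g in np.unique(levels[levels > 0]):
        lab, n_zones = ndimage.label(levels == g, structure=structure)
        if n_zones == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        np.add.at(out[g - 1], sizes - 1, 1.0)
    return out


def gldm_matrix(levels: np.ndarray, n_levels: int, alpha: int = 0) -> np.ndarray:
    """Dependence counts P[level, dependence]; dependence = 1 + equal neighbors."""
    in_mask = levels > 0
    dep = np.zeros(levels.shape, dtype=np.int64)
    for off in _OFFSETS_26:
        a, b = _shifted_views(levels, off)
        da, _ = _shifted_views(dep, off)
        hit = (a > 0) & (b > 0) & (np.abs(a.astype(np.int64) - b) <= alpha)
        da += hit
    out = np.zeros((n_levels, 27), dtype=np.float64)
    np.add.at(out, (levels[in_mask] - 1, dep[in_mask]), 1.0)
    return out


def ngtdm_table(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """NGTDM columns: n_i (count), s_i (sum of |level - neighborhood mean|).

    Voxels with no in-mask neighbor are excluded.
    """
    in_mask = levels > 0
    nb_sum = np.zeros(levels.shape, dtype=np.float64)
    nb_cnt = np.zeros(levels.shape, dtype=np.int64)
    for off in _OFFSETS_26:
        a, b = _shifted_views(levels, off)
        sa, _ = _shifted_views(nb_sum, off)
        ca, _ = _shifted_views(nb_cnt, off)
        hit = (a > 0) & (b > 0)
        sa += np.where(hit, b, 0)
        ca += hit
    use = in_mask & (nb_cnt > 0)
    diff = np.abs(levels[use] - nb_sum[use] / nb_cnt[use])
    lv = levels[use] - 1
    n_i = np.bincount(lv, minlength=n_levels).astype(np.float64)
    s_i = np.bincount(lv, weights=diff, minlength=n_levels)
    return np.stack([n_i, s_i], axis=1)


def texture_matrix(levels: np.ndarray, n_levels: int, kind: str) -> TextureMatrices:
    """Build one family's matrix/matrices from a discretized grid."""
    if n_levels < 1:
        raise ValueError("need at least one gray level")
    n_vox = int((levels > 0).sum())
    builders = {
        "glcm": glcm_matrices,
        "glrlm": glrlm_matrices,
        "glszm": glszm_matrix,
        "gldm": gldm_matrix,
        "ngtdm": ngtdm_table,
    }
    if kind not in builders:
        raise ValueError(f"unknown texture family {kind!r}")
    mat = builders[kind](levels, n_levels)
    agg = "direction-averaged" if kind in ("glcm", "glrlm") else "single"
    return TextureMatrices(kind=kind, matrix=mat, n_levels=n_levels, n_voxels=n_vox, aggregation=agg)


# --------------------------------------------------------------------------
# scalar features
# --------------------------------------------------------------------------

def _xlog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def _glcm_features_one(P: np.ndarray) -> dict[str, float]:
    g = P.shape[0]
    total = P.sum()
    if total == 0:
        return {n: 0.0 for n in FAMILY_FEATURE_NAMES["glcm"]}
    p = P / total
    i = np.arange(1, g + 1)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float((i * px).sum())
    var = float(((i - mu) ** 2 * px).sum())

    k_diff = np.arange(g)
    pd = np.bincount(np.abs(I - J).ravel(), weights=p.ravel(), minlength=g)[:g]
    k_sum = np.arange(2, 2 * g + 1)
    ps = np.bincount((I + J).ravel(), weights=p.ravel(), minlength=2 * g + 1)[2:]

    hxy = float(-_xlog2(p).sum())
    px_py = np.outer(px, px)
    hxy1 = float(-np.sum(np.where(px_py > 0, p * np.log2(np.where(px_py > 0, px_py, 1.0)), 0.0)))
    hxy2 = float(-_xlog2(px_py).sum())
    hx = float(-_xlog2(px).sum())

    da = float((k_diff * pd).sum())
    corr = float(((I * J * p).sum() - mu * mu) / var) if var > 0 else 1.0

    # maximal correlation coefficient: sqrt of second-largest eigenvalue of Q
    if g > 1 and (px > 0).sum() > 1:
        nz = px > 0
        pnz = p[np.ix_(nz, nz)]
        pxnz = px[nz]
        Q = (pnz / pxnz[:, None]) @ (pnz / pxnz[None, :]).T
        ev = np.sort(np.abs(np.linalg.eigvals(Q)))
        mcc = float(np.sqrt(max(ev[-2], 0.0))) if len(ev) > 1 else 1.0
    else:
        mcc = 1.0

    imc1 = float((hxy - hxy1) / max(hx, hx)) if max(hx, hx) > 0 else 0.0
    imc2 = float(np.sqrt(max(1.0 - np.exp(-2.0 * (hxy2 - hxy)), 0.0)))

    inv_var = float(np.sum(pd[1:] / k_diff[1:] ** 2)) if g > 1 else 0.0

    return {
        "Autocorrelation": float((I * J * p).sum()),
        "JointAverage": mu,
        "ClusterProminence": float((((I + J) - 2 * mu) ** 4 * p).sum()),
        "ClusterShade": float((((I + J) - 2 * mu) ** 3 * p).sum()),
        "ClusterTendency": float((((I + J) - 2 * mu) ** 2 * p).sum()),
        "Contrast": float(((I - J) ** 2 * p).sum()),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-_xlog2(pd).sum()),
        "DifferenceVariance": float(((k_diff - da) ** 2 * pd).sum()),
        "Id": float((pd / (1 + k_diff)).sum()),
        "Idm": float((pd / (1 + k_diff**2)).sum()),
        "Idmn": float((pd / (1 + (k_diff / g) ** 2)).sum()),
        "Idn": float((pd / (1 + k_diff / g)).sum()),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "MaximumProbability": float(p.max()),
        "MCC": mcc,
        "SumAverage": float((k_sum * ps).sum()),
        "SumEntropy": float(-_xlog2(ps).sum()),
        "SumSquares": var,
    }


def _level_size_features(P: np.ndarray, n_voxels: int, names: dict[str, str]) -> dict[str, float]:
    """Shared feature set of the level x size families (GLRLM/GLSZM/GLDM).

    ``names`` maps generic keys to the family's feature names; keys absent
    from the map are skipped (families expose different subsets).
    """
    Nr = P.sum()
    if Nr == 0:
        return {v: 0.0 for v in names.values()}
    g, smax = P.shape
    i = np.arange(1, g + 1)
    j = np.arange(1, smax + 1)
    I, J = np.meshgrid(i, j, indexing="ij")
    p = P / Nr
    pg = P.sum(axis=1)  # per level
    psz = P.sum(axis=0)  # per size
    mu_i = float((np.arange(1, g + 1) * pg).sum() / Nr)
    mu_j = float((np.arange(1, smax + 1) * psz).sum() / Nr)

    vals = {
        "small": float((P / J**2).sum() / Nr),
        "large": float((P * J**2).sum() / Nr),
        "gln": float((pg**2).sum() / Nr),
        "glnn": float((pg**2).sum() / Nr**2),
        "sn": float((psz**2).sum() / Nr),
        "snn": float((psz**2).sum() / Nr**2),
        "percentage": float(Nr / n_voxels) if n_voxels else 0.0,
        "gl_var": float((p * (I - mu_i) ** 2).sum()),
        "size_var": float((p * (J - mu_j) ** 2).sum()),
        "entropy": float(-_xlog2(p).sum()),
        "low": float((P / I**2).sum() / Nr),
        "high": float((P * I**2).sum() / Nr),
        "small_low": float((P / (I**2 * J**2)).sum() / Nr),
        "small_high": float((P * I**2 / J**2).sum() / Nr),
        "large_low": float((P * J**2 / I**2).sum() / Nr),
        "large_high": float((P * I**2 * J**2).sum() / Nr),
    }
    return {fname: vals[key] for key, fname in names.items()}


_GLRLM_NAMES = {
    "small": "ShortRunEmphasis",
    "large": "LongRunEmphasis",
    "gln": "GrayLevelNonUniformity",
    "glnn": "GrayLevelNonUniformityNormalized",
    "sn": "RunLengthNonUniformity",
    "snn": "RunLengthNonUniformityNormalized",
    "percentage": "RunPercentage",
    "gl_var": "GrayLevelVariance",
    "size_var": "RunVariance",
    "entropy": "RunEntropy",
    "low": "LowGrayLevelRunEmphasis",
    "high": "HighGrayLevelRunEmphasis",
    "small_low": "ShortRunLowGrayLevelEmphasis",
    "small_high": "ShortRunHighGrayLevelEmphasis",
    "large_low": "LongRunLowGrayLevelEmphasis",
    "large_high": "LongRunHighGrayLevelEmphasis",
}

_GLSZM_NAMES = {
    "small": "SmallAreaEmphasis",
    "large": "LargeAreaEmphasis",
    "gln": "GrayLevelNonUniformity",
    "glnn": "GrayLevelNonUniformityNormalized",
    "sn": "SizeZoneNonUniformity",
    "snn": "SizeZoneNonUniformityNormalized",
    "percentage": "ZonePercentage",
    "gl_var": "GrayLevelVariance",
    "size_var": "ZoneVariance",
    "entropy": "ZoneEntropy",
    "low": "LowGrayLevelZoneEmphasis",
    "high": "HighGrayLevelZoneEmphasis",
    "small_low": "SmallAreaLowGrayLevelEmphasis",
    "small_high": "SmallAreaHighGrayLevelEmphasis",
    "large_low": "LargeAreaLowGrayLevelEmphasis",
    "large_high": "LargeAreaHighGrayLevelEmphasis",
}

_GLDM_NAMES = {
    "small": "SmallDependenceEmphasis",
    "large": "LargeDependenceEmphasis",
    "gln": "GrayLevelNonUniformity",
    "sn": "DependenceNonUniformity",
    "snn": "DependenceNonUniformityNormalized",
    "gl_var": "GrayLevelVariance",
    "size_var": "DependenceVariance",
    "entropy": "DependenceEntropy",
    "low": "LowGrayLevelEmphasis",
    "high": "HighGrayLevelEmphasis",
    "small_low": "SmallDependenceLowGrayLevelEmphasis",
    "small_high": "SmallDependenceHighGrayLevelEmphasis",
    "large_low": "LargeDependenceLowGrayLevelEmphasis",
    "large_high": "LargeDependenceHighGrayLevelEmphasis",
}


def _ngtdm_features(table: np.ndarray, n_voxels: int) -> dict[str, float]:
    n_i, s_i = table[:, 0], table[:, 1]
    nvp = n_i.sum()
    if nvp == 0:
        return {n: 0.0 for n in FAMILY_FEATURE_NAMES["ngtdm"]}
    p_i = n_i / nvp
    i = np.arange(1, len(n_i) + 1, dtype=float)
    nz = p_i > 0
    ngp = int(nz.sum())

    coarse_den = float((p_i * s_i).sum())
    coarseness = 1.0 / coarse_den if coarse_den > 0 else 1e6

    if ngp > 1:
        Pi, Pj = np.meshgrid(p_i[nz], p_i[nz], indexing="ij")
        Ii, Jj = np.meshgrid(i[nz], i[nz], indexing="ij")
        contrast = float((Pi * Pj * (Ii - Jj) ** 2).sum() / (ngp * (ngp - 1)) * s_i.sum() / nvp)
        busy_den = float(np.abs(Ii * Pi - Jj * Pj).sum())
        busyness = coarse_den / busy_den if busy_den > 0 else 0.0
        Si, Sj = np.meshgrid(s_i[nz], s_i[nz], indexing="ij")
        complexity = float((np.abs(Ii - Jj) * (Pi * Si + Pj * Sj) / (Pi + Pj)).sum() / nvp)
        s_sum = float(s_i.sum())
        strength = float(((Pi + Pj) * (Ii - Jj) ** 2).sum() / s_sum) if s_sum > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


FAMILY_FEATURE_NAMES: dict[str, tuple[str, ...]] = {
    "glcm": (
        "Autocorrelation",
        "JointAverage",
        "ClusterProminence",
        "ClusterShade",
        "ClusterTendency",
        "Contrast",
        "Correlation",
        "DifferenceAverage",
        "DifferenceEntropy",
        "DifferenceVariance",
        "Id",
        "Idm",
        "Idmn",
        "Idn",
        "Imc1",
        "Imc2",
        "InverseVariance",
        "JointEnergy",
        "JointEntropy",
        "MaximumProbability",
        "MCC",
        "SumAverage",
        "SumEntropy",
        "SumSquares",
    ),
    "glrlm": tuple(_GLRLM_NAMES[k] for k in _GLRLM_NAMES),
    "glszm": tuple(_GLSZM_NAMES[k] for k in _GLSZM_NAMES),
    "gldm": tuple(_GLDM_NAMES[k] for k in _GLDM_NAMES),
    "ngtdm": ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength"),
}


def texture_features(tm: TextureMatrices) -> dict[str, float]:
    """Scalar features of one family; directional families are averaged."""
    if tm.kind == "glcm":
        per_dir = [_glcm_features_one(P) for P in tm.matrix]
        return {n: float(np.mean([d[n] for d in per_dir])) for n in FAMILY_FEATURE_NAMES["glcm"]}
    if tm.kind == "glrlm":
        per_dir = [_level_size_features(P, tm.n_voxels, _GLRLM_NAMES) for P in tm.matrix]
        return {n: float(np.mean([d[n] for d in per_dir])) for n in FAMILY_FEATURE_NAMES["glrlm"]}
    if tm.kind == "glszm":
        return _level_size_features(tm.matrix, tm.n_voxels, _GLSZM_NAMES)
    if tm.kind == "gldm":
        return _level_size_features(tm.matrix, tm.n_voxels, _GLDM_NAMES)
    return _ngtdm_features(tm.matrix, tm.n_voxels)
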