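"""Texture matrices against exhaustive enumeration oracles on small grids.

The oracles below re-derive every matrix family with plain Python loops
(pair walking, run walking, BFS flood fill, neighbor counting) and are
compared against the vectorized implementations on random grids up to
4x4x4, including masked-out voxels, plus the documented limit cases.
"""

import numpy as np
import pytest

from peristas.features import texture_features, texture_matrix
from peristas.features.texture import (
    DIRECTIONS_13,
    FAMILY_FEATURE_NAMES,
    glcm_matrices,
    gldm_matrix,
    glrlm_matrices,
    glszm_matrix,
    ngtdm_table,
)

RNG = np.random.default_rng(2024)
_NEIGHBORS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def random_level_grid(seed, shape=(4, 4, 4), n_levels=3, p_masked=0.3):
    rng = np.random.default_rng(seed)
    lv = rng.integers(1, n_levels + 1, size=shape)
    lv[rng.uniform(size=shape) < p_masked] = 0
    if (lv > 0).sum() < 2:
        lv[0, 0, 0], lv[0, 0, 1] = 1, 2
    return lv


def _inside(shape, p):
    return all(0 <= c < n for c, n in zip(p, shape))


def oracle_glcm(levels, n_levels):
    out = np.zeros((len(DIRECTIONS_13), n_levels, n_levels))
    for k, d in enumerate(DIRECTIONS_13):
        for p in np.ndindex(levels.shape):
            q = tuple(c + o for c, o in zip(p, d))
            if _inside(levels.shape, q) and levels[p] > 0 and levels[q] > 0:
                out[k, levels[p] - 1, levels[q] - 1] += 1
                out[k, levels[q] - 1, levels[p] - 1] += 1
    return out


def oracle_glrlm(levels, n_levels):
    max_len = max(levels.shape)
    out = np.zeros((len(DIRECTIONS_13), n_levels, max_len))
    for k, d in enumerate(DIRECTIONS_13):
        for p in np.ndindex(levels.shape):
            if levels[p] == 0:
                continue
            prev = tuple(c - o for c, o in zip(p, d))
            if _inside(levels.shape, prev) and levels[prev] == levels[p]:
                continue  # not a run start
            length, q = 1, p
            while True:
                q = tuple(c + o for c, o in zip(q, d))
                if _inside(levels.shape, q) and levels[q] == levels[p]:
                    length += 1
                else:
                    break
            out[k, levels[p] - 1, length - 1] += 1
    return out


def oracle_glszm(levels, n_levels):
    n_vox = int((levels > 0).sum())
    out = np.zeros((n_levels, max(n_vox, 1)))
    seen = np.zeros(levels.shape, bool)
    for p in np.ndindex(levels.shape):
        if levels[p] == 0 or seen[p]:
            continue
        # BFS flood fill with 26-connectivity
        stack, zone = [p], []
        seen[p] = True
        while stack:
            c = stack.pop()
            zone.append(c)
            for d in _NEIGHBORS_26:
                q = tuple(a + b for a, b in zip(c, d))
                if _inside(levels.shape, q) and not seen[q] and levels[q] == levels[p]:
                    seen[q] = True
                    stack.append(q)
        out[levels[p] - 1, len(zone) - 1] += 1
    return out


def oracle_gldm(levels, n_levels, alpha=0):
    out = np.zeros((n_levels, 27))
    for p in np.ndindex(levels.shape):
        if levels[p] == 0:
            continue
        dep = 0
        for d in _NEIGHBORS_26:
            q = tuple(a + b for a, b in zip(p, d))
            if _inside(levels.shape, q) and levels[q] > 0 and abs(levels[q] - levels[p]) <= alpha:
                dep += 1
        out[levels[p] - 1, dep] += 1
    return out


def oracle_ngtdm(levels, n_levels):
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    for p in np.ndindex(levels.shape):
        if levels[p] == 0:
            continue
        nb = [
            levels[tuple(a + b for a, b in zip(p, d))]
            for d in _NEIGHBORS_26
            if _inside(levels.shape, tuple(a + b for a, b in zip(p, d)))
        ]
        nb = [v for v in nb if v > 0]
        if not nb:
            continue
        n_i[levels[p] - 1] += 1
        s_i[levels[p] - 1] += abs(levels[p] - np.mean(nb))
    return np.stack([n_i, s_i], axis=1)


ORACLES = {
    "glcm": (glcm_matrices, oracle_glcm),
    "glrlm": (glrlm_matrices, oracle_glrlm),
    "glszm": (glszm_matrix, oracle_glszm),
    "gldm": (gldm_matrix, oracle_gldm),
    "ngtdm": (ngtdm_table, oracle_ngtdm),
}


class TestMatricesAgainstOracles:
    @pytest.mark.parametrize("family", ORACLES)
    @pytest.mark.parametrize("seed", range(8))
    def test_random_small_grids(self, family, seed):
        lv = random_level_grid(seed)
        impl, oracle = ORACLES[family]
        got, want = impl(lv, 3), oracle(lv, 3)
        assert got.shape == want.shape
        np.testing.assert_array_equal(got, want)

    @pytest.mark.parametrize("family", ORACLES)
    @pytest.mark.parametrize(
        "shape,aniso_seed", [((2, 3, 4), 50), ((4, 1, 4), 51), ((1, 1, 4), 52)]
    )
    def test_non_cubic_grids(self, family, shape, aniso_seed):
        lv = random_level_grid(aniso_seed, shape=shape, n_levels=4)
        impl, oracle = ORACLES[family]
        np.testing.assert_array_equal(impl(lv, 4), oracle(lv, 4))

    def test_glcm_two_column_toy(self):
        # levels [[1,2],[1,2]] in one slice: horizontal pairs (1,2) twice
        lv = np.array([[1, 2], [1, 2]])[:, :, None]
        M = glcm_matrices(lv, 2)
        k = DIRECTIONS_13.index((0, 1, 0))
        np.testing.assert_array_equal(M[k], [[0, 2], [2, 0]])

    def test_glszm_two_isolated_voxels(self):
        lv = np.zeros((3, 3, 3), int)
        lv[0, 0, 0] = 1
        lv[2, 2, 2] = 1
        M = glszm_matrix(lv, 1)
        assert M[0, 0] == 2  # (level 1, size 1) counted twice


class TestFeatureValues:
    def test_family_feature_counts(self):
        counts = {f: len(FAMILY_FEATURE_NAMES[f]) for f in FAMILY_FEATURE_NAMES}
        assert counts == {"glcm": 24, "glrlm": 16, "glszm": 16, "gldm": 14, "ngtdm": 5}

    def test_constant_region_limits(self):
        lv = np.ones((3, 3, 3), int)
        glcm = texture_features(texture_matrix(lv, 1, "glcm"))
        assert glcm["Contrast"] == 0.0
        assert glcm["JointEntropy"] == 0.0
        assert glcm["MaximumProbability"] == 1.0
        glrlm = texture_features(texture_matrix(lv, 1, "glrlm"))
        assert glrlm["GrayLevelNonUniformityNormalized"] == 1.0
        szm = texture_features(texture_matrix(lv, 1, "glszm"))
        assert szm["ZonePercentage"] == pytest.approx(1 / 27)
        for fam in FAMILY_FEATURE_NAMES:
            vals = texture_features(texture_matrix(lv, 1, fam))
            assert np.isfinite(list(vals.values())).all(), fam

    def test_glcm_contrast_homogeneity_brute_sum(self):
        # 4-level hand matrix: features equal the defining double sums
        rng = np.random.default_rng(5)
        lv = rng.integers(1, 5, size=(4, 4, 4))
        tm = texture_matrix(lv, 4, "glcm")
        feats = texture_features(tm)
        contrasts, homogs = [], []
        for P in tm.matrix:
            p = P / P.sum()
            c = sum(
                p[i, j] * (i - j) ** 2 for i in range(4) for j in range(4)
            )
            h = sum(p[i, j] / (1 + abs(i - j)) for i in range(4) for j in range(4))
            contrasts.append(c)
            homogs.append(h)
        assert feats["Contrast"] == pytest.approx(np.mean(contrasts), rel=1e-12)
        assert feats["Id"] == pytest.approx(np.mean(homogs), rel=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_no_nan_on_random_grids(self, seed):
        lv = random_level_grid(seed + 40, shape=(4, 4, 4), n_levels=5)
        for fam in FAMILY_FEATURE_NAMES:
            vals = texture_features(texture_matrix(lv, 5, fam))
            assert np.isfinite(list(vals.values())).all(), fam

    def test_single_level_error_guard(self):
        with pytest.raises(ValueError):
            texture_matrix(np.ones((2, 2, 2), int), 0, "glcm")
        with pytest.raises(ValueError):
            texture_matrix(np.ones((2, 2, 2), int), 1, "nope")


class TestInvariances:
    def test_rotation_invariance_of_direction_averaged_features(self):
        rng = np.random.default_rng(11)
        lv = rng.integers(1, 4, size=(5, 5, 5))
        base = {
            fam: texture_features(texture_matrix(lv, 3, fam))
            for fam in FAMILY_FEATURE_NAMES
        }
        for k in (1, 2, 3):
            rot = np.rot90(lv, k=k, axes=(0, 1)).copy()
            for fam, ref in base.items():
                got = texture_features(texture_matrix(rot, 3, fam))
                for name, v in ref.items():
                    assert got[name] == pytest.approx(v, abs=1e-6), (fam, name)
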