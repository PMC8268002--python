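"""Metric correctness of the mm-accurate morphology and VOI construction."""

import numpy as np
import pytest

from peristas.shells import (
    SHELL_DISTANCES_MM,
    annular_ring,
    build_voi_set,
    dilate_mm,
    erode_mm,
    interface_band,
    perinodular_shell,
)
from peristas.synthetic import PhantomSpec, generate_case
from peristas.volume import VoxelMask

from conftest import ball_mask, make_mask, single_voxel_mask


def brute_force_dilate(mask: VoxelMask, d: float) -> np.ndarray:
    """O(N*M) oracle: voxel centers within d mm of any mask voxel center."""
    sp = np.asarray(mask.spacing_mm)
    pts = np.argwhere(mask.grid) * sp
    out = np.zeros(mask.shape, bool)
    for idx in np.ndindex(mask.shape):
        p = np.asarray(idx) * sp
        if np.min(np.sum((pts - p) ** 2, axis=1)) <= d**2 + 1e-9:
            out[idx] = True
    return out


def brute_force_erode(mask: VoxelMask, d: float) -> np.ndarray:
    """Oracle: mask voxels farther than d mm from every non-mask voxel."""
    sp = np.asarray(mask.spacing_mm)
    if mask.grid.all():  # no background: every voxel is infinitely deep
        return mask.grid.copy()
    bg = np.argwhere(~mask.grid) * sp
    out = np.zeros(mask.shape, bool)
    for idx in np.argwhere(mask.grid):
        p = idx * sp
        if np.min(np.sum((bg - p) ** 2, axis=1)) > d**2 + 1e-9:
            out[tuple(idx)] = True
    return out


class TestDilateErode:
    def test_single_voxel_isotropic_2mm(self):
        assert dilate_mm(single_voxel_mask(), 2).voxel_count == 33

    def test_single_voxel_anisotropic_2mm(self):
        assert dilate_mm(single_voxel_mask(spacing=(1, 1, 2)), 2).voxel_count == 15

    def test_zero_distance_is_identity(self):
        m = ball_mask(3)
        assert np.array_equal(dilate_mm(m, 0).grid, m.grid)
        assert np.array_equal(erode_mm(m, 0).grid, m.grid)

    def test_negative_distance_rejected(self):
        m = single_voxel_mask()
        with pytest.raises(ValueError):
            dilate_mm(m, -1)
        with pytest.raises(ValueError):
            erode_mm(m, -0.5)

    def test_single_voxel_erodes_to_nothing(self):
        assert erode_mm(single_voxel_mask(), 1).is_empty()

    def test_cube_erosion_shrinks_by_one_layer(self):
        g = np.zeros((11, 11, 11), bool)
        g[2:9, 2:9, 2:9] = True
        assert erode_mm(make_mask(g), 1).voxel_count == 125

    @pytest.mark.parametrize(
        "mask,d",
        [
            (single_voxel_mask(), 3.0),
            (ball_mask(2.5), 2.0),
            (ball_mask(2.0, spacing=(1.0, 1.0, 2.0)), 2.5),
            (ball_mask(3.0, spacing=(0.7, 1.0, 1.3)), 1.7),
        ],
        ids=["voxel-iso", "ball-iso", "ball-aniso-z", "ball-aniso-xyz"],
    )
    def test_matches_brute_force_distance_oracle(self, mask, d):
        assert np.array_equal(dilate_mm(mask, d).grid, brute_force_dilate(mask, d))
        assert np.array_equal(erode_mm(mask, d).grid, brute_force_erode(mask, d))

    def test_erode_of_dilate_contains_convex_mask(self):
        for r in (1.5, 2.5):
            m = ball_mask(r)
            back = erode_mm(dilate_mm(m, 2), 2)
            assert m.is_subset_of(back)


class TestShellsAndBand:
    def _deep_core(self):
        lung = make_mask(np.ones((13, 13, 13), bool))
        return single_voxel_mask((13, 13, 13)), lung

    def test_single_voxel_shell_count(self):
        core, lung = self._deep_core()
        assert perinodular_shell(core, lung, 2).voxel_count == 32  # 33 - core

    def test_shell_disjoint_from_core_and_clipped(self):
        core, lung = self._deep_core()
        s = perinodular_shell(core, lung, 4)
        assert not (s.grid & core.grid).any()
        assert s.is_subset_of(lung)

    def test_core_outside_lung_rejected(self):
        lung = make_mask(np.zeros((5, 5, 5), bool))
        core = single_voxel_mask((5, 5, 5))
        with pytest.raises(ValueError, match="outside the lung"):
            perinodular_shell(core, lung, 2)

    def test_empty_core_rejected(self):
        lung = make_mask(np.ones((5, 5, 5), bool))
        with pytest.raises(ValueError, match="empty"):
            perinodular_shell(make_mask(np.zeros((5, 5, 5), bool)), lung, 2)

    def test_pleural_core_shell_stays_in_lung(self):
        lung_grid = np.zeros((15, 15, 15), bool)
        lung_grid[:8] = True  # flat pleural boundary at x=8
        core_grid = np.zeros_like(lung_grid)
        core_grid[5:8, 6:9, 6:9] = True  # touches the boundary
        s = perinodular_shell(make_mask(core_grid), make_mask(lung_grid), 4)
        assert s.voxel_count > 0
        assert not (s.grid & ~lung_grid).any()

    def test_band_covers_thin_core_entirely(self):
        core, lung = self._deep_core()
        band = interface_band(core, lung, 3)
        assert core.is_subset_of(band)

    def test_band_equals_dilation_minus_erosion(self):
        lung = make_mask(np.ones((21, 21, 21), bool))
        core = ball_mask(5.0, pad=5)
        band = interface_band(core, lung, 3)
        expected = dilate_mm(core, 3).grid & ~erode_mm(core, 3).grid
        assert np.array_equal(band.grid, expected)

    def test_annular_ring_is_shell_difference(self):
        core, lung = self._deep_core()
        ring = annular_ring(core, lung, 2, 4)
        outer = perinodular_shell(core, lung, 4)
        inner = perinodular_shell(core, lung, 2)
        assert np.array_equal(ring.grid, outer.grid & ~inner.grid)


class TestVoiSet:
    def test_eight_members_default_distances(self, small_case):
        vs = build_voi_set(small_case.core, small_case.lung)
        assert len(vs.members()) == 8
        assert vs.distances == tuple(float(d) for d in SHELL_DISTANCES_MM)

    def test_idempotent(self, small_case):
        a = build_voi_set(small_case.core, small_case.lung)
        b = build_voi_set(small_case.core, small_case.lung)
        for (na, ma), (nb, mb) in zip(a.members().items(), b.members().items()):
            assert na == nb and np.array_equal(ma.grid, mb.grid)

    def test_band_matches_interface_band_op(self, small_case):
        vs = build_voi_set(small_case.core, small_case.lung)
        direct = interface_band(small_case.core, small_case.lung, 3)
        assert np.array_equal(vs.interface.grid, direct.grid)

    def test_band_within_2mm_matches_set_algebra(self, small_case):
        # outer part of the band beyond the core within 2 mm == band & 2mm shell
        vs = build_voi_set(small_case.core, small_case.lung)
        overlap = vs.interface.grid & vs.shells[2.0].grid
        expected = perinodular_shell(small_case.core, small_case.lung, 2).grid & vs.interface.grid
        assert np.array_equal(overlap, expected)

    @pytest.mark.parametrize("seed", range(20))
    def test_random_phantom_invariants(self, seed):
        spec = PhantomSpec(grid_shape=(56, 56, 56), nodule_diameter_mm=10.0, diameter_sd_mm=2.0,
                           pleural_contact_prob=0.5)
        case = generate_case(spec, label=seed % 2, seed=seed)
        vs = build_voi_set(case.core, case.lung)
        members = vs.members()
        # nesting of cumulative shells
        for d1, d2 in zip(SHELL_DISTANCES_MM, SHELL_DISTANCES_MM[1:]):
            assert vs.shells[d1].is_subset_of(vs.shells[d2])
        for name, m in members.items():
            # no VOI voxel outside the lung
            assert m.is_subset_of(case.lung), name
            # shells disjoint from core
            if name.startswith("shell"):
                assert not (m.grid & vs.core.grid).any(), name

    def test_anisotropic_spacing_supported(self):
        spec = PhantomSpec(grid_shape=(56, 56, 44), spacing_mm=(1.0, 1.0, 1.25),
                           nodule_diameter_mm=10.0, diameter_sd_mm=1.0)
        case = generate_case(spec, label=0, seed=5)
        vs = build_voi_set(case.core, case.lung)
        assert all(m.voxel_count > 0 for m in vs.members().values())
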