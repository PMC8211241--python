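"""Ribcage → thoracic-cavity masking, stage by stage."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thoraseg import (
    CtVolume,
    PhantomSpec,
    PipelineConfig,
    build_thoracic_mask,
    clockwise_order,
    dice,
    generate_phantom,
    innermost_points,
    largest_component_3d,
    rib_regions,
    spline_outline,
    stack_slices,
    threshold_bone,
)
from thoraseg.cavity_mask import BoneMask, RibRegion


def _vol(arr):
    return CtVolume(np.asarray(arr, dtype=float), voxel_size_mm=0.1)


class TestThresholdBone:
    def test_all_zero_volume_is_an_error(self):
        with pytest.raises(ValueError, match="no bone voxels"):
            threshold_bone(_vol(np.zeros((10, 8, 8))), 0.5)

    def test_single_voxel_above_threshold(self):
        data = np.zeros((10, 8, 8))
        data[4, 4, 4] = 0.9
        m = threshold_bone(_vol(data), 0.8)
        assert m.mask.sum() == 1 and m.mask[4, 4, 4]

    def test_auto_threshold_recovers_phantom_bone(self, default_phantom):
        _, vol, lab = default_phantom
        m = threshold_bone(vol, "auto")
        assert dice(m.mask, lab.labels == 4) >= 0.95


class TestLargestComponent:
    @staticmethod
    def _flood_components(mask):
        """Independent 6-connected flood fill."""
        mask = mask.copy()
        comps = []
        while mask.any():
            seed = tuple(np.argwhere(mask)[0])
            stack, comp = [seed], set()
            while stack:
                p = stack.pop()
                if p in comp or not mask[p]:
                    continue
                comp.add(p)
                z, y, x = p
                for dz, dy, dx in ((1,0,0),(-1,0,0),(0,1,0),(0,-1,0),(0,0,1),(0,0,-1)):
                    q = (z+dz, y+dy, x+dx)
                    if all(0 <= q[i] < mask.shape[i] for i in range(3)) and mask[q]:
                        stack.append(q)
            for p in comp:
                mask[p] = False
            comps.append(comp)
        return comps

    def test_keeps_larger_of_two(self):
        m = np.zeros((12, 6, 6), dtype=bool)
        m[0:10, 0, 0] = True  # 10 voxels
        m[0:3, 4, 4] = True  # 3 voxels
        out = largest_component_3d(BoneMask(m, 0.5), 6)
        assert out.mask.sum() == 10 and out.mask[0:10, 0, 0].all()

    def test_single_component_is_identity(self):
        m = np.zeros((8, 6, 6), dtype=bool)
        m[2:5, 2:4, 2:4] = True
        out = largest_component_3d(BoneMask(m, 0.5), 26)
        assert np.array_equal(out.mask, m)

    def test_tie_breaks_to_smallest_linear_index(self):
        m = np.zeros((12, 6, 6), dtype=bool)
        m[6:11, 1, 1] = True  # appears later in scan order
        m[0:5, 3, 3] = True  # 5 voxels, earlier first voxel? (z=0 wins)
        out = largest_component_3d(BoneMask(m, 0.5), 6)
        comps = self._flood_components(m)
        assert sorted(len(c) for c in comps) == [5, 5]
        first = min(min(np.ravel_multi_index(p, m.shape) for p in c) for c in comps)
        kept = set(map(tuple, np.argwhere(out.mask)))
        winning = next(c for c in comps
                       if min(np.ravel_multi_index(p, m.shape) for p in c) == first)
        assert kept == winning


class TestStackSlices:
    def test_spreads_one_slice_across_window(self):
        m = np.zeros((20, 5, 5), dtype=bool)
        m[10, 2, 2] = True
        out = stack_slices(BoneMask(m, 0.5), 3)
        assert {int(z) for z in np.flatnonzero(out.mask.any(axis=(1, 2)))} == {9, 10, 11}

    def test_window_one_is_identity(self):
        m = np.random.default_rng(0).random((10, 5, 5)) > 0.7
        out = stack_slices(BoneMask(m, 0.5), 1)
        assert np.array_equal(out.mask, m)

    def test_full_column_unchanged(self):
        m = np.zeros((10, 5, 5), dtype=bool)
        m[:, 2, 2] = True
        out = stack_slices(BoneMask(m, 0.5), 3)
        assert np.array_equal(out.mask, m)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            stack_slices(BoneMask(np.ones((10, 5, 5), dtype=bool), 0.5), 4)


class TestRibRegions:
    def test_two_blobs_with_centroids(self):
        s = np.zeros((20, 20), dtype=bool)
        s[2:5, 2:5] = True
        s[10:14, 10:14] = True
        regs = rib_regions(s)
        assert len(regs) == 2
        cents = sorted(tuple(np.round(r.centroid, 1)) for r in regs)
        assert cents == [(3.0, 3.0), (11.5, 11.5)]

    def test_empty_slice_gives_empty_list(self):
        assert rib_regions(np.zeros((10, 10), dtype=bool)) == []

    def test_phantom_slice_shows_all_ribs_and_spine(self, default_phantom):
        spec, vol, _ = default_phantom
        stacked = stack_slices(largest_component_3d(threshold_bone(vol, "auto"), 26), 3)
        z_mid = (spec.cage_z[0] + spec.cage_z[1]) // 2
        regs = rib_regions(stacked.mask[z_mid])
        assert len(regs) == 2 * spec.rib_count + 1


class TestInnermostPoints:
    @staticmethod
    def _region_from_points(pts):
        return RibRegion(centroid=tuple(np.mean(pts, axis=0)),
                         boundary=np.asarray(pts, dtype=float), area=len(pts))

    def test_ring_keeps_inner_boundary(self):
        t = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        inner = np.column_stack([10 * np.sin(t), 10 * np.cos(t)])
        outer = np.column_stack([15 * np.sin(t), 15 * np.cos(t)])
        reg = self._region_from_points(np.vstack([inner, outer]))
        pts = innermost_points([reg], (0.0, 0.0), 0.5)
        assert np.allclose(np.hypot(pts[:, 0], pts[:, 1]), 10, atol=1e-9)

    def test_fraction_one_returns_everything(self):
        reg = self._region_from_points([[0, 1], [1, 0], [0, -1], [-1, 0]])
        assert len(innermost_points([reg], (0.0, 0.0), 1.0)) == 4

    def test_concentric_arcs_brute_force(self):
        t = np.linspace(0, np.pi, 25)
        near = np.column_stack([10 * np.sin(t), 10 * np.cos(t)])
        far = np.column_stack([20 * np.sin(t), 20 * np.cos(t)])
        regs = [self._region_from_points(near), self._region_from_points(far)]
        got = innermost_points(regs, (0.0, 0.0), 0.5)
        pool = np.vstack([near, far])
        d = np.hypot(pool[:, 0], pool[:, 1])
        expect = pool[np.argsort(d, kind="stable")[: int(np.ceil(0.5 * len(pool)))]]
        assert np.array_equal(np.sort(got, axis=0), np.sort(expect, axis=0))

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="no rib regions"):
            innermost_points([], (0.0, 0.0), 0.3)


def _cyclic_equal(a, b):
    a, b = [list(map(tuple, x)) for x in (a, b)]
    if len(a) != len(b):
        return False
    return any(a == b[i:] + b[:i] for i in range(len(b)))


class TestClockwiseOrder:
    def test_compass_points(self):
        n, e, s, w = (1, 0), (0, 1), (-1, 0), (0, -1)  # (y, x)
        out = clockwise_order(np.array([e, n, w, s], dtype=float), (0.0, 0.0))
        assert _cyclic_equal(out, np.array([n, e, s, w], dtype=float))

    def test_already_clockwise_preserved(self):
        t = np.linspace(np.pi, -np.pi, 12, endpoint=False)
        pts = np.column_stack([np.sin(t), np.cos(t)])
        out = clockwise_order(pts, (0.0, 0.0))
        assert _cyclic_equal(out, pts)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_matches_angle_sort_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(50, 2)) * 10
        out = clockwise_order(pts, (0.0, 0.0))
        ang = np.mod(np.pi - np.arctan2(out[:, 0], out[:, 1]), 2 * np.pi)
        rad = np.hypot(out[:, 0], out[:, 1])
        keys = list(zip(ang, rad))
        assert keys == sorted(keys)

    def test_coincident_points_rejected(self):
        pts = np.zeros((5, 2))
        with pytest.raises(ValueError, match="coincide"):
            clockwise_order(pts, (0.0, 0.0))


class TestSplineOutline:
    def test_circle_area_recovered(self):
        t = np.linspace(np.pi, -np.pi, 16, endpoint=False)
        pts = np.column_stack([40 + 30 * np.sin(t), 40 + 30 * np.cos(t)])
        mask = spline_outline(pts, (80, 80))
        assert mask.sum() == pytest.approx(np.pi * 30**2, rel=0.02)

    def test_square_between_eroded_and_dilated(self):
        pts = np.array([[10, 10], [10, 40], [40, 40], [40, 10]], dtype=float)
        mask = spline_outline(pts, (50, 50))
        inner = np.zeros((50, 50), dtype=bool)
        inner[12:39, 12:39] = True
        outer = np.zeros((50, 50), dtype=bool)
        outer[9:42, 9:42] = True
        assert mask[inner].all()
        assert not mask[~outer].any()

    def test_three_points_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            spline_outline(np.array([[0, 0], [0, 5], [5, 0]], dtype=float), (10, 10))


class TestBuildThoracicMask:
    def test_mask_matches_true_cavity_mid_thorax(self, default_phantom, default_run):
        _, _, lab = default_phantom
        _, parts = default_run
        mask = parts["mask"]
        cav = np.isin(lab.labels, (1, 2, 3))
        zs = mask.nonempty_slices
        third = zs[len(zs) // 3 : 2 * len(zs) // 3]
        assert dice(mask.mask[third], cav[third]) >= 0.90

    def test_mask_excludes_bone(self, default_phantom, default_run):
        _, vol, _ = default_phantom
        _, parts = default_run
        bone = largest_component_3d(threshold_bone(vol, "auto"), 26)
        assert not (parts["mask"].mask & bone.mask).any()

    def test_each_slice_single_region(self, default_run):
        from scipy import ndimage as ndi

        _, parts = default_run
        for z in parts["mask"].nonempty_slices:
            _, n = ndi.label(parts["mask"].mask[z])
            assert n == 1

    def test_adjacent_slice_areas_vary_smoothly(self, default_run):
        _, parts = default_run
        areas = parts["mask"].mask.sum(axis=(1, 2))
        pairs = [(a, b) for a, b in zip(areas[:-1], areas[1:]) if a > 0 and b > 0]
        assert all(abs(a - b) <= 0.30 * max(a, b) for a, b in pairs)

    def test_refinement_never_grows_cavity_under_blur(self):
        spec = dataclasses.replace(PhantomSpec(grid_shape=(96, 96, 64)),
                                   motion_blur_sd=1.0)
        vol, _ = generate_phantom(spec, seed=3)
        mask = build_thoracic_mask(vol, PipelineConfig())
        for z in range(vol.shape[0]):
            assert mask.mask[z].sum() <= mask.pass1_mask[z].sum()

    def test_no_bone_volume_is_an_error(self):
        v = CtVolume(np.full((12, 20, 20), 0.1), voxel_size_mm=0.1)
        with pytest.raises(ValueError):
            build_thoracic_mask(v, PipelineConfig(bone_threshold=0.8))
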