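"""Rodrigues rotations, plane propagation and curved planar reformation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tdcai.centerline import Centerline
from tdcai.phantom import make_stenosis_phantom
from tdcai.straighten import (
    assess_caliber_profile,
    initial_plane,
    propagate_planes,
    resample_on_planes,
    rotate_vector,
    straighten,
)

unit_vectors = st.tuples(
    st.floats(-1, 1), st.floats(-1, 1), st.floats(-1, 1)
).map(np.array).filter(lambda v: np.linalg.norm(v) > 1e-3).map(
    lambda v: v / np.linalg.norm(v)
)
vectors = st.tuples(
    st.floats(-10, 10), st.floats(-10, 10), st.floats(-10, 10)
).map(np.array)
angles = st.floats(-2 * np.pi, 2 * np.pi)


class TestRotateVector:
    def test_zero_angle_is_identity(self):
        v = np.array([1.0, 2.0, 3.0])
        assert np.allclose(rotate_vector(v, np.array([0, 0, 1.0]), 0.0), v, atol=1e-12)

    def test_vector_parallel_to_axis_is_invariant(self):
        u = np.array([0.0, 0.0, 1.0])
        v = 3.7 * u
        for th in (0.3, 1.1, np.pi / 2, 2.9):
            assert np.allclose(rotate_vector(v, u, th), v, atol=1e-12)

    def test_quarter_turn_about_z(self):
        got = rotate_vector(np.array([1.0, 0.0, 0.0]), np.array([0.0, 0.0, 1.0]), np.pi / 2)
        assert np.allclose(got, [0.0, 1.0, 0.0], atol=1e-12)

    def test_non_unit_axis_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            rotate_vector(np.array([1.0, 0, 0]), np.array([0, 0, 2.0]), 0.5)

    @settings(deadline=None, max_examples=200)
    @given(v=vectors, u=unit_vectors, th=angles)
    def test_norm_preserved(self, v, u, th):
        assert np.linalg.norm(rotate_vector(v, u, th)) == pytest.approx(
            np.linalg.norm(v), abs=1e-9)

    @settings(deadline=None, max_examples=100)
    @given(v=vectors, w=vectors, u=unit_vectors, th=angles)
    def test_angles_preserved(self, v, w, u, th):
        rv, rw = rotate_vector(v, u, th), rotate_vector(w, u, th)
        assert np.dot(rv, rw) == pytest.approx(np.dot(v, w), abs=1e-8)

    @settings(deadline=None, max_examples=100)
    @given(v=vectors, u=unit_vectors, t1=st.floats(0, np.pi), t2=st.floats(0, np.pi))
    def test_same_axis_rotations_compose_additively(self, v, u, t1, t2):
        a = rotate_vector(rotate_vector(v, u, t1), u, t2)
        b = rotate_vector(v, u, t1 + t2)
        assert np.allclose(a, b, atol=1e-8)


class TestInitialPlane:
    def test_grid_size_and_center(self):
        p = initial_plane(1, 1.0)
        assert p.shape == (9, 3)
        assert np.allclose(p.mean(axis=0), 0.0, atol=1e-12)

    def test_all_points_in_z_plane(self):
        p = initial_plane(4, 0.5)
        assert np.allclose(p[:, 2], 0.0)

    def test_corner_to_center_distance(self):
        m, sp = 3, 0.7
        p = initial_plane(m, sp)
        d = np.linalg.norm(p, axis=1)
        assert d.max() == pytest.approx(m * sp * np.sqrt(2))

    def test_half_size_below_one_rejected(self):
        with pytest.raises(ValueError):
            initial_plane(0, 1.0)


class TestPropagatePlanes:
    def test_straight_centerline_planes_are_translates(self):
        pts = np.stack([np.zeros(10), np.zeros(10), np.arange(10.0)], axis=1)
        stack = propagate_planes(Centerline(points=pts), half_size=2, spacing=1.0)
        base = stack.planes[0] - pts[0]
        for i in range(10):
            assert np.allclose(stack.planes[i] - pts[i], base, atol=1e-9)
        assert all(angle == 0.0 for angle, _ in stack.rotations)

    def test_quarter_arc_rotates_normal_by_90_degrees(self):
        # oracle: accumulating the analytic per-step rotations over a 90°
        # planar arc must turn the plane normal from z-hat to x-hat
        th = np.linspace(0, np.pi / 2, 200)
        pts = np.stack([10 * (1 - np.cos(th)), np.zeros_like(th), 10 * np.sin(th)], axis=1)
        cl = Centerline(points=pts)
        stack = propagate_planes(cl, half_size=1, spacing=0.5)
        # reconstruct the final normal from the plane geometry
        plane = stack.planes[-1]
        grid = plane.reshape(3, 3, 3)
        n = np.cross(grid[0, 1] - grid[1, 1], grid[1, 0] - grid[1, 1])
        n /= np.linalg.norm(n)
        assert abs(np.dot(n, [0.0, 0.0, 1.0])) < 0.02
        assert abs(abs(np.dot(n, [1.0, 0.0, 0.0])) - 1.0) < 1e-3

    def test_plane_grids_are_isometric_to_first(self):
        rng = np.random.default_rng(0)
        th = np.linspace(0, 1.2, 60)
        pts = np.stack([5 * np.sin(th), th**2, 30 * th], axis=1)
        stack = propagate_planes(Centerline(points=pts), half_size=2, spacing=0.8)
        d0 = np.linalg.norm(stack.planes[0][:, None] - stack.planes[0][None], axis=-1)
        for i in (10, 30, 59):
            di = np.linalg.norm(stack.planes[i][:, None] - stack.planes[i][None], axis=-1)
            assert np.allclose(di, d0, atol=1e-9)

    def test_rotation_axes_are_unit(self):
        th = np.linspace(0, 1.0, 30)
        pts = np.stack([3 * np.sin(th), np.zeros_like(th), 20 * th], axis=1)
        stack = propagate_planes(Centerline(points=pts), half_size=1, spacing=1.0)
        for angle, axis in stack.rotations:
            if angle > 0:
                assert np.linalg.norm(axis) == pytest.approx(1.0, abs=1e-12)

    def test_antiparallel_tangents_rejected(self):
        pts = np.array([[0, 0, 0], [0, 0, 1.0], [0, 0, 0.0], [0, 0, 1.0]])
        with pytest.raises(ValueError):
            propagate_planes(Centerline(points=pts), half_size=1, spacing=1.0)


class TestResample:
    def test_uniform_volume_stays_uniform(self):
        vol = np.full((30, 20, 20), 77.0)
        pts = np.stack([np.full(10, 10.0), np.full(10, 10.0), np.linspace(5, 25, 10)], axis=1)
        stack = propagate_planes(Centerline(points=pts), half_size=3, spacing=1.0)
        sv = resample_on_planes(vol, stack, (1.0, 1.0, 1.0), (0, 0, 0), step_mm=1.0)
        assert np.allclose(sv.values, 77.0)

    def test_straightening_straight_tube_is_identity_crop(self, straight_tube_series):
        values, mask = straight_tube_series
        pts = np.stack([np.full(33, 10.0), np.full(33, 10.0), np.arange(4.0, 37.0)], axis=1)
        sv = straighten(values, Centerline(points=pts), (1.0, 1.0, 1.0), (0, 0, 0),
                        step_mm=1.0, half_size_mm=10.0, in_plane_spacing=1.0)
        m = sv.values.shape[1] // 2
        crop = values[4:37, 10 - m : 10 + m + 1, 10 - m : 10 + m + 1]
        # direct crop oracle; interpolation error only at the rasterized edge
        assert sv.values.shape == crop.shape
        interior = np.zeros_like(crop, dtype=bool)
        interior[:, 1:-1, 1:-1] = True
        diff = np.abs(sv.values - crop)
        assert np.median(diff) == 0.0
        assert (diff < 1e-6).mean() > 0.9

    def test_curved_tube_sections_have_expected_area(self):
        mask, sten, dila, curve, geom = make_stenosis_phantom(
            seed=5, stenosis_interval=(15, 25), dilation_interval=(35, 45))
        seeds_pts = (curve.point(3.0), curve.point(curve.length - 3.0))
        from tdcai.centerline import extract_centerline

        cl = extract_centerline(mask, geom["spacing"], geom["origin"], seeds_pts)
        sv = straighten(mask.astype(np.float32), cl, geom["spacing"], geom["origin"],
                        step_mm=0.5, half_size_mm=10.0, sentinel=0.0)
        lumen = sv.values >= 0.5
        areas = lumen.sum(axis=(1, 2)) * sv.in_plane_spacing**2
        # slices in the untouched baseline region: pi * 3^2 within 15%
        s = np.arange(len(areas)) * sv.step_mm
        baseline = (s > 5) & (s < 10)
        assert np.all(np.abs(areas[baseline] - np.pi * 9) / (np.pi * 9) < 0.15)

    def test_all_samples_outside_grid_rejected(self):
        vol = np.zeros((10, 10, 10))
        pts = np.stack([np.full(5, 500.0), np.full(5, 500.0), np.linspace(500, 505, 5)], axis=1)
        stack = propagate_planes(Centerline(points=pts), half_size=2, spacing=1.0)
        with pytest.raises(ValueError, match="outside"):
            resample_on_planes(vol, stack, (1.0, 1.0, 1.0), (0, 0, 0), step_mm=1.0)


class TestCaliberProfile:
    def test_constant_radius_tube_has_no_flags(self, straight_tube_series):
        values, _ = straight_tube_series
        pts = np.stack([np.full(29, 10.0), np.full(29, 10.0), np.arange(5.0, 34.0)], axis=1)
        sv = straighten(values / 300.0, Centerline(points=pts), (1.0, 1.0, 1.0), (0, 0, 0),
                        step_mm=1.0, half_size_mm=10.0, in_plane_spacing=1.0, sentinel=0.0)
        profile = assess_caliber_profile(sv, lumen_threshold=0.5)
        assert profile.stenosis_intervals == []
        assert profile.dilation_intervals == []

    def test_stenosis_and_dilation_flagged_in_truth_intervals(self):
        mask, sten, dila, curve, geom = make_stenosis_phantom(seed=6)
        seeds_pts = (curve.point(3.0), curve.point(curve.length - 3.0))
        from tdcai.centerline import extract_centerline

        cl = extract_centerline(mask, geom["spacing"], geom["origin"], seeds_pts)
        sv = straighten(mask.astype(np.float32), cl, geom["spacing"], geom["origin"],
                        step_mm=0.5, half_size_mm=10.0, sentinel=0.0)
        profile = assess_caliber_profile(sv, lumen_threshold=0.5)
        assert profile.stenosis_intervals and profile.dilation_intervals

        # area at the stenosis floor ~ factor^2 = 25% of baseline
        floor = profile.areas_mm2[profile.min_area_index]
        assert floor / profile.median_area == pytest.approx(0.25, abs=0.08)

    def test_empty_lumen_rejected(self):
        from tdcai.straighten import StraightenedVolume

        sv = StraightenedVolume(values=np.zeros((5, 7, 7)), step_mm=0.5, in_plane_spacing=0.5)
        with pytest.raises(ValueError, match="lumen"):
            assess_caliber_profile(sv, lumen_threshold=0.5)
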