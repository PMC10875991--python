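"""Wall extraction, meshing, centroid graph and shortest-path centerline."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.spatial import cKDTree

from tdcai.centerline import (
    Centerline,
    build_mesh,
    centerline_deviation,
    compute_tangents,
    cross_section_centroids,
    extract_centerline,
    extract_wall,
    shortest_path_centerline,
)
from tdcai.core import index_to_world
from tdcai.phantom import make_deviation_phantom


def _ball(radius_vox, pad=3):
    n = 2 * (radius_vox + pad) + 1
    zz, yy, xx = np.mgrid[:n, :n, :n] - (n // 2)
    return (zz**2 + yy**2 + xx**2) <= radius_vox**2


def _tube(radius_vox=6, length=40, n=21):
    zz, yy, xx = np.mgrid[:length, :n, :n]
    mask = ((yy - n // 2) ** 2 + (xx - n // 2) ** 2) <= radius_vox**2
    mask[:3] = False
    mask[-3:] = False
    return mask


class TestExtractWall:
    def test_ball_wall_is_thin_shell_with_empty_interior(self):
        mask = _ball(10)
        wall = extract_wall(mask)
        assert wall.sum() < mask.sum() * 0.5
        assert not ndimage.binary_erosion(mask, iterations=2)[wall].any()
        # interior voxels survive in mask minus wall
        assert (mask & ~wall).sum() > 0

    def test_single_voxel_mask_is_its_own_wall(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        wall = extract_wall(mask)
        assert wall.sum() == 1 and wall[2, 2, 2]

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            extract_wall(np.zeros((4, 4, 4), dtype=bool))

    def test_tube_wall_count_close_to_lateral_surface(self):
        r, length = 6, 40
        mask = _tube(r, length)
        wall = extract_wall(mask)
        # analytic lateral surface voxelization ~ 2 pi r h (+ two end caps)
        h = length - 6
        expected_lateral = 2 * np.pi * r * h
        caps = 2 * np.pi * r**2
        assert wall.sum() == pytest.approx(expected_lateral + caps, rel=0.35)


class TestBuildMesh:
    def test_ball_mesh_area_close_to_sphere(self):
        spacing = 1.0
        mask = _ball(10)
        wall = extract_wall(mask)
        mesh = build_mesh(wall, (spacing,) * 3)
        assert mesh.area == pytest.approx(4 * np.pi * 10**2, rel=0.05)

    def test_tube_mesh_closed_genus_zero(self):
        mesh = build_mesh(extract_wall(_tube()), (1.0, 1.0, 1.0))
        assert mesh.is_watertight
        assert mesh.euler_number == 2  # sphere topology

    def test_vertices_near_wall_voxels(self):
        spacing = 1.0
        wall = extract_wall(_ball(8))
        mesh = build_mesh(wall, (spacing,) * 3)
        wall_pts = index_to_world(np.argwhere(wall), (spacing,) * 3, (0, 0, 0))
        d, _ = cKDTree(wall_pts).query(mesh.vertices)
        assert d.max() <= spacing * np.sqrt(3)

    def test_planar_mask_rejected(self):
        mask = np.zeros((5, 9, 9), dtype=bool)
        mask[2, 2:7, 2:7] = True
        with pytest.raises(ValueError, match="planar|degenerate"):
            build_mesh(mask, (1.0, 1.0, 1.0))


class TestCrossSectionCentroids:
    def test_straight_tube_centroids_on_axis(self):
        mask = _tube()
        mesh = build_mesh(extract_wall(mask), (1.0, 1.0, 1.0))
        cg = cross_section_centroids(mesh, ([10, 10, 6], [10, 10, 34]), step_mm=1.0)
        cents = np.array([c for sl in cg.slices for c in sl])
        # all centroids within half a voxel of the axis x=y=10
        assert np.abs(cents[:, 0] - 10).max() < 0.5
        assert np.abs(cents[:, 1] - 10).max() < 0.5

    def test_junction_slices_produce_extra_contours(self):
        mask, curve, geom = make_deviation_phantom(1, seed=3)
        mesh = build_mesh(extract_wall(mask), geom["spacing"], geom["origin"])
        seeds = (curve.point(3.0), curve.point(curve.length - 3.0))
        cg = cross_section_centroids(mesh, seeds, step_mm=1.0)
        assert max(len(sl) for sl in cg.slices) > 1

    def test_centroid_matches_analytic_circle_center(self):
        mask = _tube()
        mesh = build_mesh(extract_wall(mask), (1.0, 1.0, 1.0))
        sec = mesh.section(plane_origin=[10, 10, 20], plane_normal=[0, 0, 1])
        poly = sec.discrete[0]
        vertex_mean = poly[:-1].mean(axis=0)
        from tdcai.centerline import _polygon_centroid

        area_weighted, area = _polygon_centroid(poly, np.array([0.0, 0.0, 1.0]))
        assert np.linalg.norm(area_weighted - vertex_mean) < 0.1
        assert np.allclose(area_weighted[:2], [10, 10], atol=0.2)
        assert area == pytest.approx(np.pi * 6.0**2, rel=0.1)

    def test_seed_far_outside_mesh_rejected(self):
        mesh = build_mesh(extract_wall(_tube()), (1.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="outside"):
            cross_section_centroids(mesh, ([200, 200, 200], [10, 10, 30]))


class TestShortestPathCenterline:
    def test_straight_tube_path_is_the_axis(self):
        spacing = 1.0
        mask = _tube()
        cl = extract_centerline(mask, (spacing,) * 3, (0, 0, 0),
                                ([10, 10, 6], [10, 10, 34]))
        axis = Centerline(points=np.stack(
            [np.full(50, 10.0), np.full(50, 10.0), np.linspace(3, 37, 50)], axis=1))
        mean, sd, mx = centerline_deviation(cl, axis)
        assert mx < 0.5 * spacing

    def test_path_avoids_branch_centroids(self):
        mask, curve, geom = make_deviation_phantom(3, seed=8)
        seeds = (curve.point(3.0), curve.point(curve.length - 3.0))
        cl = extract_centerline(mask, geom["spacing"], geom["origin"], seeds)
        d, _ = cKDTree(curve.sample(0.02)[0]).query(cl.points)
        assert d.max() < 1.0  # branch centroids sit many mm off-axis

    def test_every_point_inside_voi_mask(self):
        mask, curve, geom = make_deviation_phantom(0, seed=9)
        seeds = (curve.point(3.0), curve.point(curve.length - 3.0))
        cl = extract_centerline(mask, geom["spacing"], geom["origin"], seeds)
        idx = np.round(
            (cl.points[:, ::-1] - np.asarray(geom["origin"])[::-1])
            / np.asarray(geom["spacing"])
        ).astype(int)
        assert mask[idx[:, 0], idx[:, 1], idx[:, 2]].all()

    def test_path_length_at_least_euclidean_seed_distance(self):
        mask, curve, geom = make_deviation_phantom(0, seed=12)
        seeds = (curve.point(3.0), curve.point(curve.length - 3.0))
        cl = extract_centerline(mask, geom["spacing"], geom["origin"], seeds)
        assert cl.length >= np.linalg.norm(cl.points[-1] - cl.points[0]) - 1e-9


class TestTangents:
    def test_unit_norm_everywhere(self):
        rng = np.random.default_rng(2)
        pts = np.cumsum(rng.normal(size=(30, 3)) + [0, 0, 2], axis=0)
        t = compute_tangents(pts)
        assert np.allclose(np.linalg.norm(t, axis=1), 1.0)

    def test_straight_line_tangents_all_equal(self):
        pts = np.stack([np.zeros(10), np.zeros(10), np.arange(10.0)], axis=1)
        t = compute_tangents(pts)
        assert np.allclose(t, [0, 0, 1])


class TestCenterlineDeviation:
    def test_identical_curves_zero(self):
        pts = np.stack([np.zeros(20), np.zeros(20), np.linspace(0, 10, 20)], axis=1)
        cl = Centerline(points=pts)
        assert centerline_deviation(cl, cl) == (0.0, 0.0, 0.0)

    def test_rigid_lateral_offset_reported_exactly(self):
        pts = np.stack([np.zeros(20), np.zeros(20), np.linspace(0, 10, 20)], axis=1)
        shifted = pts + [0.2, 0.0, 0.0]
        mean, sd, mx = centerline_deviation(Centerline(points=shifted),
                                            Centerline(points=pts))
        assert mean == pytest.approx(0.2, abs=1e-6)
        assert mx == pytest.approx(0.2, abs=1e-6)
        assert sd == pytest.approx(0.0, abs=1e-6)

    def test_converges_under_reference_refinement(self):
        rng = np.random.default_rng(4)
        pts = np.cumsum(rng.normal(size=(15, 3)) + [0, 0, 3], axis=0)
        ref = Centerline(points=pts)
        probe = Centerline(points=pts + rng.normal(0, 0.1, size=pts.shape))
        coarse = centerline_deviation(probe, ref, ref_step=0.5)
        fine = centerline_deviation(probe, ref, ref_step=0.01)
        finer = centerline_deviation(probe, ref, ref_step=0.005)
        assert abs(fine[0] - finer[0]) < abs(coarse[0] - finer[0]) + 1e-9
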