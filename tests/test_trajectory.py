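"""Back-projection, two-ray triangulation and trajectory reprojection."""

import numpy as np
import pytest
from scipy.optimize import minimize

from pedreg.geometry import Pose6D, pose_to_transform, project_point, detector_point_to_pixel
from pedreg.drr import CTVolume
from pedreg.phantom import PhantomSpec, insert_marker, make_vertebra_phantom, plan_trajectory
from pedreg.trajectory import (
    DegenerateTriangulationError,
    Ray3D,
    Trajectory3D,
    backproject_pixel,
    closest_point_between_rays,
    cumulate_axial_slices,
    map_trajectory,
    reproject_trajectory,
)


def brute_force_closest(ray_a, ray_b):
    """Independent oracle: direct 2D minimisation over the ray parameters."""

    def f(st):
        return np.sum((ray_a.point_at(st[0]) - ray_b.point_at(st[1])) ** 2)

    res = minimize(
        f,
        [0.0, 0.0],
        method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-24, "maxiter": 50000, "maxfev": 50000},
    )
    p1, p2 = ray_a.point_at(res.x[0]), ray_b.point_at(res.x[1])
    return (p1 + p2) / 2, float(np.linalg.norm(p1 - p2))


class TestClosestPoint:
    def test_perpendicular_skew_lines(self):
        a = Ray3D([0, 0, 0], [1, 0, 0])
        b = Ray3D([0, 0, 2], [0, 1, 0])
        mid, gap = closest_point_between_rays(a, b)
        assert np.allclose(mid, [0, 0, 1], atol=1e-12)
        assert gap == pytest.approx(2.0, abs=1e-12)

    def test_intersecting_rays(self):
        a = Ray3D([0, 0, 0], [1, 1, 0])
        b = Ray3D([4, 0, 0], [-1, 1, 0])
        mid, gap = closest_point_between_rays(a, b)
        assert gap == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(mid, [2, 2, 0], atol=1e-9)

    def test_symmetric_under_swap(self, rng):
        a = Ray3D(rng.normal(size=3) * 10, rng.normal(size=3))
        b = Ray3D(rng.normal(size=3) * 10, rng.normal(size=3))
        m1, g1 = closest_point_between_rays(a, b)
        m2, g2 = closest_point_between_rays(b, a)
        assert g1 == g2
        assert np.allclose(m1, m2)

    def test_matches_brute_force_on_random_skew_pairs(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            a = Ray3D(rng.uniform(-50, 50, 3), rng.normal(size=3))
            b = Ray3D(rng.uniform(-50, 50, 3), rng.normal(size=3))
            mid, gap = closest_point_between_rays(a, b)
            mid_o, gap_o = brute_force_closest(a, b)
            assert abs(gap - gap_o) < 1e-6
            # the midpoint tolerance is set by the oracle's simplex
            # termination, not by the closed-form solution under test
            assert np.linalg.norm(mid - mid_o) < 1e-4

    def test_near_parallel_rejected_with_both_rays_named(self):
        a = Ray3D([0, 0, 0], [1, 0, 0])
        b = Ray3D([0, 5, 0], [1, 1e-5, 0])
        with pytest.raises(DegenerateTriangulationError, match="nearly parallel"):
            closest_point_between_rays(a, b)

    def test_midpoint_minimises_sum_of_squared_ray_distances(self, rng):
        a = Ray3D(rng.uniform(-20, 20, 3), rng.normal(size=3))
        b = Ray3D(rng.uniform(-20, 20, 3), rng.normal(size=3))
        mid, _ = closest_point_between_rays(a, b)
        f = lambda p: a.distance_to_point(p) ** 2 + b.distance_to_point(p) ** 2
        f_mid = f(mid)
        for _ in range(200):
            assert f_mid <= f(mid + rng.normal(0, 1.0, 3)) + 1e-9


class TestBackprojection:
    def test_principal_pixel_identity_pose_gives_central_axis(self, small_camera):
        ray = backproject_pixel(small_camera, Pose6D(), small_camera.principal_pixel, (0, 0, 0))
        assert np.allclose(ray.origin, small_camera.source)
        assert np.allclose(ray.direction, small_camera.axis, atol=1e-12)

    def test_project_backproject_roundtrip(self, small_camera, rng):
        pose = Pose6D(5.0, -8.0, 2.0, 6.0, -3.0, 1.0)
        center = np.array([2.0, -1.0, 4.0])
        T = pose_to_transform(pose, center)
        for _ in range(20):
            X = rng.uniform(-30, 30, 3)
            det = project_point(small_camera, T.apply(X))
            px, _ = detector_point_to_pixel(small_camera, det)
            ray = backproject_pixel(small_camera, pose, px, center)
            assert ray.distance_to_point(X) < 1e-6


class TestMapTrajectory:
    def test_consistent_views_triangulate_exactly(self, case):
        m = case.truth.marker2d_exact
        traj = map_trajectory(
            m["ap"]["head"], m["ap"]["tail"], m["lat"]["head"], m["lat"]["tail"],
            case.rig.ap, case.rig.lat,
            case.truth.pose["ap"], case.truth.pose["lat"],
            case.truth.rotation_center,
        )
        assert traj.head_gap < 1e-6 and traj.tail_gap < 1e-6
        assert traj.length == pytest.approx(30.0, abs=1e-6)
        assert np.allclose(traj.head, case.truth.marker_head3d, atol=1e-6)
        assert np.allclose(traj.tail, case.truth.marker_tail3d, atol=1e-6)

    def test_annotation_perturbation_grows_gaps_boundedly(self, case):
        m = case.truth.marker2d_exact
        gaps, lengths = [], []
        for eps in (1.0, 2.0):
            traj = map_trajectory(
                m["ap"]["head"] + [eps, 0.0], m["ap"]["tail"] + [eps, 0.0],
                m["lat"]["head"], m["lat"]["tail"],
                case.rig.ap, case.rig.lat,
                case.truth.pose["ap"], case.truth.pose["lat"],
                case.truth.rotation_center,
            )
            gaps.append(traj.head_gap)
            lengths.append(abs(traj.length - 30.0))
        assert gaps[1] > gaps[0] > 1e-3
        assert gaps[1] == pytest.approx(2 * gaps[0], rel=0.05)  # linear response
        # length error bounded by annotation shift x pixel size, demagnified
        spacing = case.rig.ap.pixel_spacing_u
        assert all(l < 2 * 2.0 * spacing for l in lengths)

    def test_swapped_lateral_labels_warn(self, case):
        m = case.truth.marker2d_exact
        with pytest.warns(UserWarning, match="swapped"):
            map_trajectory(
                m["ap"]["head"], m["ap"]["tail"],
                m["lat"]["tail"], m["lat"]["head"],
                case.rig.ap, case.rig.lat,
                case.truth.pose["ap"], case.truth.pose["lat"],
                case.truth.rotation_center,
            )

    def test_reprojection_closes_the_loop(self, case):
        m = case.truth.marker2d_exact
        traj = map_trajectory(
            m["ap"]["head"], m["ap"]["tail"], m["lat"]["head"], m["lat"]["tail"],
            case.rig.ap, case.rig.lat,
            case.truth.pose["ap"], case.truth.pose["lat"],
            case.truth.rotation_center,
        )
        for view in ("ap", "lat"):
            seg = reproject_trajectory(
                traj, case.rig.camera(view), case.truth.pose[view], case.truth.rotation_center
            )
            assert np.linalg.norm(seg[0] - m[view]["head"]) < 1e-6
            assert np.linalg.norm(seg[1] - m[view]["tail"]) < 1e-6
            # ordering along the marker axis is preserved
            d_actual = m[view]["tail"] - m[view]["head"]
            d_reproj = seg[1] - seg[0]
            assert float(d_actual @ d_reproj) > 0

    def test_trajectory_invariants(self):
        with pytest.raises(ValueError):
            Trajectory3D([0, 0, 0], [0, 0, 0], 0.0, 0.0)
        with pytest.raises(ValueError):
            Trajectory3D([0, 0, 0], [1, 0, 0], -1.0, 0.0)


class TestCumulateAxial:
    def test_single_slice_range_returns_that_slice(self):
        vox = np.arange(2 * 3 * 4, dtype=float).reshape(2, 3, 4)
        vol = CTVolume(vox, (1, 1, 1), (0, 0, 0))
        out = cumulate_axial_slices(vol, (2, 2))
        assert np.array_equal(out, vox[:, :, 2])

    def test_sum_of_two_identical_slices_doubles(self):
        sl = np.random.default_rng(0).normal(size=(5, 6))
        vox = np.stack([sl, sl], axis=2)
        vol = CTVolume(vox, (1, 1, 1), (0, 0, 0))
        assert np.allclose(cumulate_axial_slices(vol, (0, 1), "sum"), 2 * sl)
        assert np.allclose(cumulate_axial_slices(vol, (0, 1), "mean"), sl)

    def test_empty_range_rejected(self):
        vol = CTVolume(np.zeros((4, 4, 4)), (1, 1, 1), (0, 0, 0))
        with pytest.raises(ValueError):
            cumulate_axial_slices(vol, (3, 2))
        with pytest.raises(ValueError):
            cumulate_axial_slices(vol, (0, 4))

    def test_marker_appears_as_brightest_line(self):
        spec = PhantomSpec()
        vol, _ = make_vertebra_phantom(spec)
        entry, _, target = plan_trajectory(spec, "L")
        d = target - entry
        vol, head, tail = insert_marker(vol, entry, d, hu=spec.hu_marker)
        k = int(round(head[2] / spec.spacing[2]))
        img = cumulate_axial_slices(vol, (k, k))
        # sample the cumulated image along the known axial path
        ts = np.linspace(0.05, 0.95, 25)
        pts = head[None, :2] + ts[:, None] * (tail - head)[None, :2]
        idx = np.round(pts).astype(int)
        on_line = img[idx[:, 0], idx[:, 1]]
        assert on_line.min() >= np.quantile(img, 0.99)
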