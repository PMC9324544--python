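"""Landmark registration: cost function, cropping, CMA-ES pose recovery."""

import numpy as np
import pytest

from pedreg.drr import CTVolume
from pedreg.geometry import Pose6D
from pedreg.phantom import make_case
from pedreg.registration import (
    CorrespondenceError,
    OptConfig,
    UnderdeterminedError,
    crop_vertebra,
    initialize_pose,
    mpde,
    project_landmarks,
    register_vertebra,
    register_view,
)


class TestCrop:
    def make_volume(self):
        rng = np.random.default_rng(0)
        vox = rng.normal(0, 100, (30, 40, 20))
        return CTVolume(vox, (0.5, 1.0, 2.0), (-10.0, 5.0, 3.0))

    def test_full_extent_box_is_identity(self):
        vol = self.make_volume()
        sub = crop_vertebra(vol, ((0, 30), (0, 40), (0, 20)))
        assert np.array_equal(sub.voxels, vol.voxels)
        assert np.allclose(sub.origin, vol.origin)

    def test_world_coordinates_preserved(self):
        vol = self.make_volume()
        sub = crop_vertebra(vol, ((10, 20), (10, 20), (10, 20)))
        # voxel (10+i, 10+j, 10+k) of the parent is voxel (i, j, k) of the crop
        assert np.allclose(sub.voxel_center((0, 0, 0)), vol.voxel_center((10, 10, 10)))
        assert np.allclose(sub.voxel_center((5, 2, 7)), vol.voxel_center((15, 12, 17)))
        assert np.array_equal(sub.voxels, vol.voxels[10:20, 10:20, 10:20])

    def test_crop_commutes_with_projection(self, small_camera):
        # a landmark expressed in world mm projects identically whether the
        # volume around it was cropped or not (origin bookkeeping)
        vol = self.make_volume()
        sub = crop_vertebra(vol, ((5, 25), (5, 35), (5, 15)))
        lm_world = vol.voxel_center((12, 17, 9))
        lm_in_crop = sub.voxel_center((7, 12, 4))
        assert np.allclose(lm_world, lm_in_crop, atol=1e-12)

    def test_empty_or_outside_box_rejected(self):
        vol = self.make_volume()
        with pytest.raises(ValueError):
            crop_vertebra(vol, ((5, 5), (0, 40), (0, 20)))
        with pytest.raises(ValueError):
            crop_vertebra(vol, ((0, 31), (0, 40), (0, 20)))


class TestMpde:
    def test_identical_sets_give_zero(self):
        pts = {"a": (1.0, 2.0), "b": (-3.0, 0.5)}
        assert mpde(pts, dict(pts)) == 0.0

    def test_three_four_five_triangle(self):
        assert mpde({"a": (0.0, 0.0)}, {"a": (3.0, 4.0)}) == pytest.approx(5.0)

    def test_hand_computed_three_pairs(self):
        proj = {"a": (0, 0), "b": (0, 0), "c": (0, 0)}
        targ = {"a": (1, 0), "b": (0, 2), "c": (2, 2 * np.sqrt(2))}
        # norms 1, 2 and sqrt(4 + 8) = 2*sqrt(3); mean = (3 + 2*sqrt(3)) / 3
        assert mpde(proj, targ) == pytest.approx(2.1547005383792515, abs=1e-12)

    def test_key_mismatch_rejected(self):
        with pytest.raises(CorrespondenceError):
            mpde({"a": (0, 0)}, {"b": (0, 0)})
        with pytest.raises(CorrespondenceError):
            mpde({}, {})


class TestProjectLandmarks:
    def test_identity_pose_on_axis_hits_principal_pixel(self, small_camera):
        lms = {"c": small_camera.source + 0.6 * (small_camera.cop - small_camera.source)}
        px = project_landmarks(lms, Pose6D(), small_camera, rotation_center=(0, 0, 0))
        assert np.allclose(px["c"], small_camera.principal_pixel, atol=1e-9)

    def test_in_plane_translation_moves_pattern_rigidly(self, small_camera):
        # landmarks at a common depth all translate by the same pixel vector
        base = small_camera.source + 0.5 * (small_camera.cop - small_camera.source)
        lms = {
            f"p{i}": base + du * small_camera.detector_u_axis + dv * small_camera.detector_v_axis
            for i, (du, dv) in enumerate([(0, 0), (8, -5), (-12, 3), (4, 9)])
        }
        center = np.mean(list(lms.values()), axis=0)
        a = project_landmarks(lms, Pose6D(), small_camera, center)
        b = project_landmarks(lms, Pose6D(t_x=3.0, t_z=-2.0), small_camera, center)
        deltas = np.array([b[k] - a[k] for k in lms])
        assert np.max(np.abs(deltas - deltas[0])) < 1e-9
        assert np.linalg.norm(deltas[0]) > 0

    def test_out_of_frustum_landmark_excluded_with_warning(self, small_camera):
        lms = {
            "ok": np.array([0.0, 0.0, 0.0]),
            "behind": small_camera.source - 50.0 * small_camera.axis,
        }
        with pytest.warns(UserWarning, match="behind"):
            px = project_landmarks(lms, Pose6D(), small_camera, (0, 0, 0))
        assert "ok" in px and "behind" not in px


class TestRegisterView:
    def test_init_at_truth_converges_immediately(self, case):
        l3d = case.truth.landmarks3d
        res = register_view(
            l3d,
            case.landmarks2d["ap"],
            case.rig.ap,
            init=case.truth.pose["ap"],
            config=OptConfig(seed=0),
            rotation_center=case.truth.rotation_center,
        )
        assert res.converged
        assert res.final_mpde < 1e-9
        assert res.n_evaluations == 1

    def test_underdetermined_and_mismatched_sets(self, case, small_camera):
        l3d = case.truth.landmarks3d
        with pytest.raises(UnderdeterminedError):
            register_view(l3d, {"body_centroid": np.zeros(2)}, small_camera)
        with pytest.raises(CorrespondenceError):
            register_view(
                l3d, {"nope%d" % i: np.zeros(2) for i in range(4)}, small_camera
            )

    def test_trace_running_minimum_non_increasing(self, case):
        res = register_view(
            case.truth.landmarks3d,
            case.landmarks2d["lat"],
            case.rig.lat,
            config=OptConfig(seed=2, max_evals=500),
            rotation_center=case.truth.rotation_center,
        )
        best = res.best_so_far()
        assert np.all(np.diff(best) <= 0)
        assert res.n_evaluations <= 500

    def test_parameter_recovery_from_perturbed_inits(self, case):
        """Noise-free targets, inits perturbed up to +/-10 mm / 10 deg:
        median final mPDE is far below a pixel and in-plane parameters
        are recovered to < 1 mm / 1 deg (depth stays weakly identified)."""
        l3d = case.truth.landmarks3d
        targets = dict(case.truth.landmarks2d_exact["ap"])
        truth = case.truth.pose["ap"].as_array()
        finals, poses = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            init = Pose6D.from_array(
                truth + rng.uniform(-1, 1, 6) * [10, 10, 10, 10, 10, 10]
            )
            res = register_view(
                l3d,
                targets,
                case.rig.ap,
                init=init,
                config=OptConfig(seed=100 + seed),
                rotation_center=case.truth.rotation_center,
            )
            finals.append(res.final_mpde)
            poses.append(res.pose.as_array())
        finals = np.array(finals)
        err = np.abs(np.array(poses) - truth)
        assert np.median(finals) < 0.1
        # AP view axis is y: in-plane translations are t_x, t_z;
        # in-plane rotation is theta_y
        assert np.median(err[:, 3]) < 1.0 and np.median(err[:, 5]) < 1.0
        assert np.median(err[:, 1]) < 1.0

    def test_noisy_targets_reach_the_annotation_noise_floor(self, case):
        """0.5 px landmark noise: the registered residual settles near the
        Monte-Carlo expectation E||eps|| = sigma * sqrt(pi/2) (detector mm),
        reduced by the fitted degrees of freedom."""
        l3d = case.truth.landmarks3d
        cam = case.rig.lat
        sigma_px = 0.5
        sigma_mm = sigma_px * cam.pixel_spacing_u
        mc = np.random.default_rng(0).normal(0, sigma_mm, (200000, 2))
        floor = np.mean(np.linalg.norm(mc, axis=1))  # Monte-Carlo oracle
        assert floor == pytest.approx(sigma_mm * np.sqrt(np.pi / 2), rel=0.01)
        finals = []
        for seed in range(8):
            rng = np.random.default_rng(1000 + seed)
            noisy = {
                k: v + rng.normal(0, sigma_px, 2)
                for k, v in case.truth.landmarks2d_exact["lat"].items()
            }
            res = register_view(
                l3d, noisy, cam,
                config=OptConfig(seed=seed),
                rotation_center=case.truth.rotation_center,
            )
            finals.append(res.final_mpde)
        med = np.median(finals)
        assert 0.2 * floor < med < 1.5 * floor


class TestRegisterVertebra:
    def test_independent_mode_consistent_views(self, case):
        ap, lat = register_vertebra(
            case.truth.landmarks3d,
            case.landmarks2d["ap"],
            case.landmarks2d["lat"],
            case.rig.ap,
            case.rig.lat,
            config=OptConfig(seed=0),
            rotation_center=case.truth.rotation_center,
        )
        assert ap.final_mpde < 0.05 and lat.final_mpde < 0.05
        assert ap.seed != lat.seed  # independent optimizer streams

    def test_joint_mode_not_worse_than_independent(self, case):
        sums_ind, sums_joint = [], []
        for seed in range(5):
            cfg = OptConfig(seed=seed)
            ap, lat = register_vertebra(
                case.truth.landmarks3d,
                case.landmarks2d["ap"],
                case.landmarks2d["lat"],
                case.rig.ap,
                case.rig.lat,
                config=cfg,
                rotation_center=case.truth.rotation_center,
            )
            japc, jlat = register_vertebra(
                case.truth.landmarks3d,
                case.landmarks2d["ap"],
                case.landmarks2d["lat"],
                case.rig.ap,
                case.rig.lat,
                config=cfg,
                rotation_center=case.truth.rotation_center,
                mode="joint",
            )
            assert np.array_equal(japc.pose.as_array(), jlat.pose.as_array())
            sums_ind.append(ap.final_mpde + lat.final_mpde)
            sums_joint.append(japc.final_mpde + jlat.final_mpde)
        # on consistent views the shared-pose optimum is the same global
        # optimum, so joint mode tracks the independent solutions closely
        assert np.median(sums_joint) <= np.median(sums_ind) + 0.05

    def test_unknown_mode_rejected(self, case):
        with pytest.raises(ValueError):
            register_vertebra(
                case.truth.landmarks3d,
                case.landmarks2d["ap"],
                case.landmarks2d["lat"],
                case.rig.ap,
                case.rig.lat,
                mode="simultaneous",
            )


class TestInitializePose:
    def test_initializer_reduces_initial_cost(self, case):
        from pedreg.registration import _make_cost

        l3d = case.truth.landmarks3d
        for view in ("ap", "lat"):
            cam = case.rig.camera(view)
            cost, _ = _make_cost(
                l3d, case.landmarks2d[view], cam, case.truth.rotation_center
            )
            init = initialize_pose(
                l3d, case.landmarks2d[view], cam, case.truth.rotation_center
            )
            assert cost(init.as_array()) < cost(np.zeros(6))

    def test_already_aligned_case_returns_near_zero(self, case):
        # landmarks generated at zero pose need (almost) no initial shift
        from pedreg.registration import _make_cost
        exact0 = make_case(true_pose=Pose6D(), render=False)
        init = initialize_pose(
            exact0.truth.landmarks3d,
            exact0.landmarks2d["ap"],
            exact0.rig.ap,
            exact0.truth.rotation_center,
        )
        assert np.linalg.norm(init.as_array()) < 1.0
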