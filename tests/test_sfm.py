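import copy

import numpy as np
import pytest
from conftest import synthetic_track_model

from shoremapper.geometry import (
    CameraIntrinsics,
    CameraPose,
    project_points,
    random_rotation,
    rodrigues,
)
from shoremapper.georef import horn_align
from shoremapper.sfm import (
    ReconstructionModel,
    bundle_adjust,
    initialize_pair,
    register_view,
    run_incremental_sfm,
)
from shoremapper.sfm.incremental import (
    AlreadyRegisteredError,
    InitializationError,
    RegistrationError,
    select_initial_pair,
    triangulate_new_tracks,
)
from shoremapper.sfm.pnp import PnPError, p3p_solutions, pnp_ransac


def fresh_model(tg, kps, bands, intr, focal_error=1.0):
    priors = {}
    for b, k in intr.items():
        priors[b] = CameraIntrinsics(k.focal * focal_error, k.cx, k.cy,
                                     width=k.width, height=k.height)
    return ReconstructionModel(track_graph=tg, keypoints=kps,
                               image_bands=dict(bands), intrinsics=priors)


class TestP3P:
    def test_exact_recovery_general_configurations(self):
        rng = np.random.default_rng(3)
        ok = 0
        for _ in range(100):
            R = random_rotation(rng)
            C = rng.normal(0, 5, 3)
            Xc = np.column_stack([rng.uniform(-0.4, 0.4, 3),
                                  rng.uniform(-0.4, 0.4, 3),
                                  rng.uniform(5, 20, 3)])
            Pw = Xc @ R + C
            b = Xc / np.linalg.norm(Xc, axis=1, keepdims=True)
            sols = p3p_solutions(Pw, b)
            best = min((max(np.abs(s.R - R).max(), np.abs(s.C - C).max())
                        for s in sols), default=np.inf)
            ok += best < 1e-5
        assert ok == 100

    def test_pnp_on_nearly_planar_scene(self):
        """P3P has no planar degeneracy (shore terrain is near-planar)."""
        rng = np.random.default_rng(4)
        intr = CameraIntrinsics(450.0, 319.5, 239.5)
        pose = CameraPose(R=np.array([[1, 0, 0], [0, -1, 0], [0, 0, -1.0]]),
                          C=np.array([0, 0, 15.0]))
        X = np.column_stack([rng.uniform(-8, 8, 200), rng.uniform(-6, 6, 200),
                             rng.normal(0, 0.02, 200)])
        uv, _ = project_points(X, pose, intr)
        est, inl = pnp_ransac(X, uv + rng.normal(0, 0.3, uv.shape), intr, seed=1)
        assert inl.sum() == 200
        assert np.linalg.norm(est.C - pose.C) < 0.02

    def test_pnp_rejects_with_outliers_flagged(self):
        rng = np.random.default_rng(5)
        intr = CameraIntrinsics(450.0, 319.5, 239.5)
        pose = CameraPose(R=np.array([[1, 0, 0], [0, -1, 0], [0, 0, -1.0]]),
                          C=np.array([1.0, -2.0, 14.0]))
        X = np.column_stack([rng.uniform(-8, 8, 150), rng.uniform(-6, 6, 150),
                             rng.uniform(-0.5, 0.5, 150)])
        uv, _ = project_points(X, pose, intr)
        uv[:40] = rng.uniform(0, 480, (40, 2))  # gross outliers
        est, inl = pnp_ransac(X, uv, intr, threshold_px=2.0, seed=2)
        assert inl[40:].all()
        assert not inl[:40].any()
        assert np.linalg.norm(est.C - pose.C) < 0.01

    def test_too_few_correspondences(self):
        intr = CameraIntrinsics(450.0, 319.5, 239.5)
        with pytest.raises(PnPError):
            pnp_ransac(np.zeros((4, 3)), np.zeros((4, 2)), intr)


class TestInitializePair:
    def test_noiseless_relative_pose_within_0p1_degree(self):
        # strong 3D structure: the 8-point essential estimate needs
        # non-planar support to be well conditioned
        tg, kps, bands, poses, intr, X = synthetic_track_model(
            n_views=4, n_points=500, seed=1, relief=5.0)
        model = ReconstructionModel(track_graph=tg, keypoints=kps,
                                    image_bands=dict(bands),
                                    intrinsics=dict(intr))  # calibrated case
        pair = select_initial_pair(model)
        initialize_pair(model, pair)
        a, b = pair
        # compare relative rotation with truth (gauge: first camera frame)
        R_rel_est = model.poses[b].R @ model.poses[a].R.T
        R_rel_true = poses[b].R @ poses[a].R.T
        dR = R_rel_est @ R_rel_true.T
        ang = np.degrees(np.arccos(np.clip((np.trace(dR) - 1) / 2, -1, 1)))
        assert ang < 0.1
        # translation direction in the first camera's frame
        t_est = model.poses[a].R @ (model.poses[b].C - model.poses[a].C)
        t_true = poses[a].R @ (poses[b].C - poses[a].C)
        cos = np.dot(t_est, t_true) / (np.linalg.norm(t_est) * np.linalg.norm(t_true))
        assert np.degrees(np.arccos(np.clip(abs(cos), -1, 1))) < 0.1

    def test_zero_baseline_pair_rejected_for_parallax(self):
        from shoremapper.tracks import Track, TrackGraph

        rng = np.random.default_rng(2)
        intr = CameraIntrinsics(450.0, 319.5, 239.5)
        C = np.array([0.0, 0.0, 15.0])
        nadir = np.array([[1, 0, 0], [0, -1, 0], [0, 0, -1.0]])
        p1 = CameraPose(R=nadir, C=C)
        p2 = CameraPose(R=rodrigues([0.0, 0.0, 0.05]) @ nadir, C=C)  # pure rotation
        X = np.column_stack([rng.uniform(-6, 6, 200), rng.uniform(-5, 5, 200),
                             rng.uniform(-0.5, 0.5, 200)])
        kps = {"a": [], "b": []}
        tracks = []
        for j in range(200):
            uv1, _ = project_points(X[j][None], p1, intr)
            uv2, _ = project_points(X[j][None], p2, intr)
            tracks.append(None)
            kps["a"].append(uv1[0])
            kps["b"].append(uv2[0])
        from shoremapper.tracks import Track

        tg = TrackGraph(tracks=[Track(observations={"a": j, "b": j})
                                for j in range(200)])
        model = ReconstructionModel(
            track_graph=tg, keypoints={k: np.array(v) for k, v in kps.items()},
            image_bands={"a": "colour", "b": "colour"}, intrinsics={"colour": intr},
        )
        with pytest.raises(InitializationError):
            initialize_pair(model, ("a", "b"), min_inliers=50)


class TestRegisterView:
    def test_incremental_third_view_pose_accuracy(self):
        tg, kps, bands, poses, intr, X = synthetic_track_model(
            n_views=5, n_points=500, seed=3)
        model = fresh_model(tg, kps, bands, intr)
        pair = select_initial_pair(model)
        initialize_pair(model, pair)
        remaining = [i for i in sorted(kps) if i not in model.poses]
        register_view(model, remaining[0], seed=1)
        triangulate_new_tracks(model)
        # gauge-align camera centres to truth and compare the new pose
        reg = model.registration_order
        tf, res = horn_align(np.array([model.poses[i].C for i in reg]),
                             np.array([poses[i].C for i in reg]),
                             estimate_scale_flag=True)
        baseline = np.linalg.norm(poses[reg[0]].C - poses[reg[1]].C)
        assert np.sqrt((res**2).mean()) < 0.01 * baseline

    def test_reregistering_is_an_error(self):
        tg, kps, bands, poses, intr, X = synthetic_track_model(seed=4)
        model = fresh_model(tg, kps, bands, intr)
        pair = select_initial_pair(model)
        initialize_pair(model, pair)
        with pytest.raises(AlreadyRegisteredError):
            register_view(model, pair[0])

    def test_view_without_triangulated_overlap_skipped(self):
        tg, kps, bands, poses, intr, X = synthetic_track_model(seed=5)
        model = fresh_model(tg, kps, bands, intr)
        pair = select_initial_pair(model)
        initialize_pair(model, pair)
        model.points.clear()   # nothing triangulated any more
        other = next(i for i in sorted(kps) if i not in model.poses)
        with pytest.raises(RegistrationError):
            register_view(model, other)


class TestBundleAdjust:
    def _ground_truth_model(self, seed=6, noise_px=0.0):
        tg, kps, bands, poses, intr, X = synthetic_track_model(
            n_views=6, n_points=400, seed=seed, noise_px=noise_px)
        model = ReconstructionModel(track_graph=tg, keypoints=kps,
                                    image_bands=dict(bands),
                                    intrinsics=dict(intr),
                                    poses=dict(poses),
                                    registration_order=sorted(poses))
        triangulate_new_tracks(model, min_angle_deg=0.5)
        return model, poses, intr

    def test_model_at_optimum_stays_put(self):
        model, poses, intr = self._ground_truth_model()
        bundle_adjust(model, ftol=1e-12)
        before = {i: model.poses[i].C.copy() for i in model.poses}
        f_before = model.intrinsics["colour"].focal
        bundle_adjust(model, ftol=1e-12)
        for i in model.poses:
            assert np.abs(model.poses[i].C - before[i]).max() < 1e-6
        assert abs(model.intrinsics["colour"].focal - f_before) < 1e-4

    def test_objective_non_increasing(self):
        model, _, _ = self._ground_truth_model(noise_px=1.0)
        info = bundle_adjust(model)
        assert info["cost_after"] <= info["cost_before"] + 1e-9

    def test_recovers_from_perturbed_initialisation(self):
        """Pose noise ~1 deg / point noise ~1%: reprojection returns < 0.3 px."""
        model, poses, intr = self._ground_truth_model()
        rng = np.random.default_rng(0)
        for i in list(model.poses)[1:]:
            p = model.poses[i]
            model.poses[i] = CameraPose(
                R=rodrigues(rng.normal(0, 0.01, 3)) @ p.R,
                C=p.C + rng.normal(0, 0.1, 3),
            )
        for j in model.points:
            model.points[j] = model.points[j] + rng.normal(0, 0.05, 3)
        info = bundle_adjust(model, ftol=1e-12, max_iters=200)
        assert info["rmse_px"] < 0.3

    def test_reprojection_rmse_tracks_feature_noise(self):
        """With 1 px Gaussian noise the converged RMSE sits near 1 px."""
        model, _, _ = self._ground_truth_model(noise_px=1.0)
        info = bundle_adjust(model, ftol=1e-12, max_iters=200)
        assert 0.5 < info["rmse_px"] < 1.5


class TestRunIncrementalSfm:
    def test_noiseless_synthetic_flight_focal_within_1pct(self):
        tg, kps, bands, poses, intr, X = synthetic_track_model(
            n_views=8, n_points=800, seed=7, two_bodies=True)
        model = run_incremental_sfm(tg, kps, bands,
                                    fresh_model(tg, kps, bands, intr,
                                                focal_error=0.96).intrinsics,
                                    seed=1)
        assert model.n_registered == 8
        assert model.reprojection_rmse < 0.1
        for b in model.intrinsics:
            assert abs(model.intrinsics[b].focal / intr[b].focal - 1.0) < 0.01
        reg = model.registration_order
        tf, res = horn_align(np.array([model.poses[i].C for i in reg]),
                             np.array([poses[i].C for i in reg]),
                             estimate_scale_flag=True)
        assert np.sqrt((res**2).mean()) < 0.01 * 15.0

    def test_colour_only_subset_builds(self):
        tg, kps, bands, poses, intr, X = synthetic_track_model(
            n_views=5, n_points=500, seed=8, two_bodies=False)
        model = run_incremental_sfm(tg, kps, bands, dict(intr), seed=2,
                                    focal_sweep=False)
        assert model.n_registered >= 4

    def test_cheirality_all_points_in_front(self):
        tg, kps, bands, poses, intr, X = synthetic_track_model(seed=9)
        model = run_incremental_sfm(tg, kps, bands, dict(intr), seed=3,
                                    focal_sweep=False)
        for j, P in model.points.items():
            for img, _ in model.track_observations(j):
                if img in model.poses:
                    assert model.poses[img].transform(P[None])[0, 2] > 0

    def test_similarity_gauge_freedom_is_unobservable(self):
        """Applying a similarity to the true scene leaves all image
        observations unchanged: the reconstruction cannot distinguish them."""
        from shoremapper.georef import SimilarityTransform

        tg, kps, bands, poses, intr, X = synthetic_track_model(seed=10)
        rng = np.random.default_rng(1)
        tf = SimilarityTransform(scale=2.7, R=random_rotation(rng),
                                 t=rng.normal(0, 10, 3))
        for iid, pose in poses.items():
            p2 = CameraPose(R=pose.R @ tf.R.T, C=tf.apply(pose.C))
            uv1, _ = project_points(X[:50], pose, intr[bands[iid]])
            uv2, _ = project_points(tf.apply(X[:50]), p2, intr[bands[iid]])
            assert np.abs(uv1 - uv2).max() < 1e-6
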