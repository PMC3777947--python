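"""Incremental reconstruction driver.

Start from the best two-view seed (most inliers x widest triangulation
angle), then repeatedly register the unplaced image that sees the most
already-triangulated points (robust PnP), triangulate newly-completed
tracks, and interleave bundle adjustment with outlier pruning until no image
can be added.  Colour and near-infrared frames live in one model: cross-band
tracks are what glue the two surveys together.
"""

from __future__ import annotations

import logging

import numpy as np

from ..geometry import (
    CameraIntrinsics,
    CameraPose,
    nearest_rotation,
    project_points,
    triangulate_linear,
    triangulation_angles,
)
from ..tracks import TrackGraph
from .bundle import bundle_adjust, focal_sweep_refine
from .model import ReconstructionModel
from .pnp import PnPError, pnp_ransac

log = logging.getLogger(__name__)


class InitializationError(RuntimeError):
    pass


class RegistrationError(RuntimeError):
    pass


class AlreadyRegisteredError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# two-view initialisation
# ---------------------------------------------------------------------------

def _eight_point_essential(xn1: np.ndarray, xn2: np.ndarray) -> np.ndarray | None:
    """8-point estimate of E from normalised camera coordinates."""
    if xn1.shape[0] < 8:
        return None
    u1, v1 = xn1[:, 0], xn1[:, 1]
    u2, v2 = xn2[:, 0], xn2[:, 1]
    A = np.column_stack(
        [u2 * u1, u2 * v1, u2, v2 * u1, v2 * v1, v2, u1, v1, np.ones_like(u1)]
    )
    _, sv, Vt = np.linalg.svd(A)
    if sv[-2] < 1e-12 * max(sv[0], 1e-300):
        return None
    E = Vt[-1].reshape(3, 3)
    U, _, Vt2 = np.linalg.svd(E)
    return U @ np.diag([1.0, 1.0, 0.0]) @ Vt2


def _decompose_essential(E: np.ndarray):
    U, _, Vt = np.linalg.svd(E)
    if np.linalg.det(U) < 0:
        U = -U
    if np.linalg.det(Vt) < 0:
        Vt = -Vt
    W = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    R1 = nearest_rotation(U @ W @ Vt)
    R2 = nearest_rotation(U @ W.T @ Vt)
    t = U[:, 2]
    return [(R1, t), (R1, -t), (R2, t), (R2, -t)]


def relative_pose_from_tracks(
    xn1: np.ndarray, xn2: np.ndarray
) -> tuple[CameraPose, CameraPose, np.ndarray] | None:
    """Cheirality-disambiguated relative pose from normalised correspondences.

    Returns (pose1=identity, pose2, triangulated points) or None.  The
    baseline is normalised to 1: the reconstruction is scale-less.
    """
    E = _eight_point_essential(xn1, xn2)
    if E is None:
        return None
    pose1 = CameraPose(R=np.eye(3), C=np.zeros(3))
    best = None
    dummy = CameraIntrinsics(focal=1.0, cx=0.0, cy=0.0)
    for R, t in _decompose_essential(E):
        pose2 = CameraPose(R=R, C=-R.T @ t)
        from ..geometry import triangulate_two_view

        X = triangulate_two_view(pose1, pose2, dummy, dummy, xn1, xn2)
        z1 = pose1.transform(X)[:, 2]
        z2 = pose2.transform(X)[:, 2]
        good = np.isfinite(X).all(axis=1) & (z1 > 0) & (z2 > 0)
        n_good = int(good.sum())
        if best is None or n_good > best[0]:
            best = (n_good, pose2, X, good)
    n_good, pose2, X, good = best
    if n_good < max(8, 0.5 * xn1.shape[0]):
        return None  # no clearly cheirality-positive solution
    return pose1, pose2, X


def _pair_covisibility(tracks: TrackGraph) -> dict[tuple[str, str], list[int]]:
    cov: dict[tuple[str, str], list[int]] = {}
    for j, t in enumerate(tracks.tracks):
        imgs = sorted(t.observations)
        for a_i in range(len(imgs)):
            for b_i in range(a_i + 1, len(imgs)):
                cov.setdefault((imgs[a_i], imgs[b_i]), []).append(j)
    return cov


def initialize_pair(
    model: ReconstructionModel,
    pair: tuple[str, str],
    shared_tracks: list[int] | None = None,
    min_inliers: int = 100,
    min_median_angle_deg: float = 1.5,
    reproj_px: float = 4.0,
) -> float:
    """Seed the model from one image pair; returns the median parallax (deg).

    Raises :class:`InitializationError` for low-parallax (or otherwise
    degenerate) pairs.
    """
    a, b = pair
    if shared_tracks is None:
        shared_tracks = [
            j for j, t in enumerate(model.track_graph.tracks)
            if a in t.observations and b in t.observations
        ]
    if len(shared_tracks) < min_inliers:
        raise InitializationError(
            f"pair {pair} has {len(shared_tracks)} shared tracks < {min_inliers}"
        )
    intr_a = model.intrinsics[model.image_bands[a]]
    intr_b = model.intrinsics[model.image_bands[b]]
    uv_a = np.vstack([model.keypoints[a][model.track_graph.tracks[j].observations[a]]
                      for j in shared_tracks])
    uv_b = np.vstack([model.keypoints[b][model.track_graph.tracks[j].observations[b]]
                      for j in shared_tracks])
    xn1 = np.column_stack(intr_a.pixel_to_normalized(uv_a[:, 0], uv_a[:, 1]))
    xn2 = np.column_stack(intr_b.pixel_to_normalized(uv_b[:, 0], uv_b[:, 1]))
    res = relative_pose_from_tracks(xn1, xn2)
    if res is None:
        raise InitializationError(f"pair {pair} is degenerate (essential estimation failed)")
    pose1, pose2, X = res
    angles = triangulation_angles(X, pose1.C, pose2.C)
    med_angle = float(np.nanmedian(angles))
    if med_angle < min_median_angle_deg:
        raise InitializationError(
            f"pair {pair} parallax {med_angle:.2f} deg < {min_median_angle_deg}"
        )
    model.poses[a] = pose1
    model.poses[b] = pose2
    model.registration_order.extend([a, b])
    # keep well-conditioned triangulations only
    for k, j in enumerate(shared_tracks):
        Xj = X[k]
        if not np.all(np.isfinite(Xj)):
            continue
        ok = True
        for img, intr in ((a, intr_a), (b, intr_b)):
            uv_obs = model.keypoints[img][model.track_graph.tracks[j].observations[img]]
            proj, z = project_points(Xj[None, :], model.poses[img], intr)
            if z[0] <= 0 or np.linalg.norm(proj[0] - uv_obs) > reproj_px:
                ok = False
                break
        if ok and angles[k] > min_median_angle_deg / 2.0:
            model.points[j] = Xj
    if len(model.points) < min_inliers // 2:
        # undo
        model.poses.clear()
        model.registration_order.clear()
        model.points.clear()
        raise InitializationError(f"pair {pair}: too few clean triangulations")
    return med_angle


def select_initial_pair(
    model: ReconstructionModel,
    min_inliers: int = 100,
    n_candidates: int = 12,
    min_median_angle_deg: float = 1.5,
) -> tuple[str, str]:
    """Try the most covisible pairs; score = inliers x median angle."""
    cov = _pair_covisibility(model.track_graph)
    ranked = sorted(cov.items(), key=lambda kv: -len(kv[1]))[:n_candidates]
    best_pair, best_score = None, -np.inf
    for pair, shared in ranked:
        if len(shared) < min_inliers:
            continue
        trial = ReconstructionModel(
            track_graph=model.track_graph, keypoints=model.keypoints,
            image_bands=model.image_bands, intrinsics=dict(model.intrinsics),
        )
        try:
            angle = initialize_pair(trial, pair, shared,
                                    min_inliers=min_inliers,
                                    min_median_angle_deg=min_median_angle_deg)
        except InitializationError:
            continue
        score = len(trial.points) * min(angle, 30.0)
        if score > best_score:
            best_pair, best_score = pair, score
    if best_pair is None:
        raise InitializationError("no viable initial pair (all low-parallax or degenerate)")
    return best_pair


# ---------------------------------------------------------------------------
# incremental growth
# ---------------------------------------------------------------------------

def register_view(
    model: ReconstructionModel,
    image_id: str,
    seed: int = 0,
    pnp_px: float = 4.0,
    min_corr: int = 6,
) -> int:
    """Register one image by robust PnP; returns the number of inliers."""
    if image_id in model.poses:
        raise AlreadyRegisteredError(f"{image_id} is already registered")
    X, uv = [], []
    for j in model.points:
        t = model.track_graph.tracks[j]
        if image_id in t.observations and (j, image_id) not in model.removed_obs:
            X.append(model.points[j])
            uv.append(model.keypoints[image_id][t.observations[image_id]])
    if len(X) < min_corr:
        raise RegistrationError(
            f"{image_id}: only {len(X)} 2D-3D correspondences (< {min_corr})"
        )
    intr = model.intrinsics[model.image_bands[image_id]]
    try:
        pose, inl = pnp_ransac(np.asarray(X), np.asarray(uv), intr,
                               threshold_px=pnp_px, seed=seed)
    except PnPError as e:
        raise RegistrationError(f"{image_id}: {e}") from e
    model.poses[image_id] = pose
    model.registration_order.append(image_id)
    return int(inl.sum())


def triangulate_new_tracks(
    model: ReconstructionModel,
    candidate_tracks=None,
    reproj_px: float = 4.0,
    min_angle_deg: float = 2.0,
) -> int:
    """Triangulate untriangulated tracks with >= 2 registered observations."""
    n_new = 0
    iterator = (
        candidate_tracks if candidate_tracks is not None
        else range(len(model.track_graph.tracks))
    )
    for j in iterator:
        if j in model.points:
            continue
        obs = [
            (img, kp) for img, kp in model.track_observations(j) if img in model.poses
        ]
        if len(obs) < 2:
            continue
        entries = []
        for img, kp in obs:
            uv = model.keypoints[img][kp]
            entries.append((model.poses[img],
                            model.intrinsics[model.image_bands[img]], uv[0], uv[1]))
        X = triangulate_linear(entries)
        if not np.all(np.isfinite(X)):
            continue
        # acceptance: cheirality + reprojection in every view + parallax
        ok = True
        for (img, kp), (pose, intr, u, v) in zip(obs, entries):
            proj, z = project_points(X[None, :], pose, intr)
            if z[0] <= 0 or np.linalg.norm(proj[0] - (u, v)) > reproj_px:
                ok = False
                break
        if not ok:
            continue
        centres = [model.poses[img].C for img, _ in obs]
        max_angle = 0.0
        for ci in range(len(centres)):
            for cj in range(ci + 1, len(centres)):
                ang = triangulation_angles(X[None, :], centres[ci], centres[cj])[0]
                max_angle = max(max_angle, float(ang))
        if max_angle < min_angle_deg:
            continue
        model.points[j] = X
        n_new += 1
    return n_new


def prune_observations(
    model: ReconstructionModel, max_px: float = 4.0
) -> tuple[int, int]:
    """Drop observations beyond ``max_px`` reprojection error, then points
    left with < 2 observations.  Returns (n_obs_removed, n_points_removed)."""
    n_obs = 0
    for j in list(model.points):
        for img, kp in model.track_observations(j):
            if img not in model.poses:
                continue
            intr = model.intrinsics[model.image_bands[img]]
            proj, z = project_points(model.points[j][None, :], model.poses[img], intr)
            err = np.linalg.norm(proj[0] - model.keypoints[img][kp])
            if err > max_px or z[0] <= 0:
                model.removed_obs.add((j, img))
                n_obs += 1
    n_pts = 0
    for j in list(model.points):
        reg_obs = [img for img, _ in model.track_observations(j) if img in model.poses]
        if len(reg_obs) < 2:
            del model.points[j]
            n_pts += 1
    return n_obs, n_pts


def run_incremental_sfm(
    track_graph: TrackGraph,
    keypoints: dict[str, np.ndarray],
    image_bands: dict[str, str],
    intrinsics: dict[str, CameraIntrinsics],
    seed: int = 0,
    pnp_px: float = 4.0,
    prune_px: float = 4.0,
    min_tri_angle_deg: float = 2.0,
    huber_px: float = 2.0,
    ba_growth: float = 1.4,
    final_ftol: float = 1e-10,
    focal_sweep: bool = True,
    min_init_inliers: int = 100,
) -> ReconstructionModel:
    """Full incremental SfM over all images present in the track graph."""
    all_images = sorted(keypoints)
    if len(all_images) < 2:
        raise InitializationError("need >= 2 images")
    model = ReconstructionModel(
        track_graph=track_graph,
        keypoints=keypoints,
        image_bands=dict(image_bands),
        intrinsics={b: intrinsics[b] for b in {image_bands[i] for i in all_images}},
    )

    pair = select_initial_pair(model, min_inliers=min_init_inliers)
    initialize_pair(model, pair, min_inliers=min_init_inliers,
                    min_median_angle_deg=1.5)
    log.info("initialised from pair %s with %d points", pair, len(model.points))
    # intrinsics stay frozen at their priors while the model grows: releasing
    # focal/distortion on few views of near-planar terrain locks in a
    # deformed solution that later bundle adjustments cannot escape
    bundle_adjust(model, huber_px=huber_px, ftol=1e-8, optimize_intrinsics=False)

    next_ba = max(4, int(np.ceil(model.n_registered * ba_growth)))
    rng = np.random.default_rng((seed, 271))
    failures: dict[str, int] = {}
    while True:
        remaining = [i for i in all_images if i not in model.poses
                     and failures.get(i, 0) < 3]
        if not remaining:
            break
        # most 2D-3D correspondences first
        def n_corr(img):
            return sum(
                1 for j in model.points
                if img in model.track_graph.tracks[j].observations
            )
        scored = sorted(((n_corr(i), i) for i in remaining), reverse=True)
        progressed = False
        for count, img in scored:
            if count < 6:
                continue
            try:
                n_inl = register_view(model, img, seed=int(rng.integers(2**31)),
                                      pnp_px=pnp_px)
            except RegistrationError as e:
                failures[img] = failures.get(img, 0) + 1
                log.info("skipped %s (%s)", img, e)
                continue
            cand = [
                j for j, t in enumerate(track_graph.tracks)
                if img in t.observations and j not in model.points
            ]
            n_new = triangulate_new_tracks(model, cand, reproj_px=prune_px,
                                           min_angle_deg=min_tri_angle_deg)
            log.info("registered %s: %d PnP inliers, %d new points", img, n_inl, n_new)
            progressed = True
            break
        if not progressed:
            break
        if model.n_registered >= next_ba:
            bundle_adjust(model, huber_px=huber_px, ftol=1e-7,
                          optimize_intrinsics=False, max_iters=40)
            prune_observations(model, max_px=prune_px)
            next_ba = max(model.n_registered + 3,
                          int(np.ceil(model.n_registered * ba_growth)))

    # final adjustments: all views in, now self-calibrate both bodies.
    # The focal sweep guards against the quasi-planar focal/height ambiguity.
    bundle_adjust(model, huber_px=huber_px, ftol=final_ftol, max_iters=150)
    prune_observations(model, max_px=prune_px)
    if focal_sweep:
        focal_sweep_refine(model, huber_px=huber_px)
    bundle_adjust(model, huber_px=huber_px, ftol=final_ftol, max_iters=150)
    model.skipped_images = [i for i in all_images if i not in model.poses]
    model.update_rmse()
    log.info("SfM done: %d/%d views, %d points, RMSE %.3f px",
             model.n_registered, len(all_images), len(model.points),
             model.reprojection_rmse)
    return model
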