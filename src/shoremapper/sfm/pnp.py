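"""Robust perspective-n-point pose estimation.

Minimal solver: the classical three-point resection (Grunert's quartic),
which is free of the planar degeneracy that afflicts DLT-style solvers —
essential here, because shore terrain is close to a plane.  The up-to-four
P3P solutions are disambiguated inside RANSAC by inlier count, and the best
pose is polished by Levenberg-Marquardt on the inlier reprojection error.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

from ..geometry import (
    CameraIntrinsics,
    CameraPose,
    inverse_rodrigues,
    project_points,
    rodrigues,
)


class PnPError(RuntimeError):
    pass


def p3p_solutions(Pw: np.ndarray, bearings: np.ndarray) -> list[CameraPose]:
    """All P3P poses for 3 world points and 3 unit bearing vectors.

    Grunert's formulation: solve the quartic in the ratio of the unknown
    camera-to-point distances, recover the three distances, and fit the
    rigid world->camera transform to the reconstructed camera-frame points.
    """
    P1, P2, P3 = Pw
    j1, j2, j3 = bearings
    a = np.linalg.norm(P2 - P3)
    b = np.linalg.norm(P1 - P3)
    c = np.linalg.norm(P1 - P2)
    if min(a, b, c) < 1e-12:
        return []
    cos_alpha = float(np.dot(j2, j3))
    cos_beta = float(np.dot(j1, j3))
    cos_gamma = float(np.dot(j1, j2))
    a2b = (a * a - c * c) / (b * b)
    b2b = (b * b - c * c) / (b * b)
    b2a = (b * b - a * a) / (b * b)
    apc = (a * a + c * c) / (b * b)
    A4 = (a2b - 1.0) ** 2 - 4.0 * c * c / (b * b) * cos_alpha**2
    A3 = 4.0 * (
        a2b * (1.0 - a2b) * cos_beta
        - (1.0 - apc) * cos_alpha * cos_gamma
        + 2.0 * c * c / (b * b) * cos_alpha**2 * cos_beta
    )
    A2 = 2.0 * (
        a2b**2
        - 1.0
        + 2.0 * a2b**2 * cos_beta**2
        + 2.0 * b2b * cos_alpha**2
        - 4.0 * apc * cos_alpha * cos_beta * cos_gamma
        + 2.0 * b2a * cos_gamma**2
    )
    A1 = 4.0 * (
        -a2b * (1.0 + a2b) * cos_beta
        + 2.0 * a * a / (b * b) * cos_gamma**2 * cos_beta
        - (1.0 - apc) * cos_alpha * cos_gamma
    )
    A0 = (1.0 + a2b) ** 2 - 4.0 * a * a / (b * b) * cos_gamma**2
    coeffs = np.array([A4, A3, A2, A1, A0])
    if not np.all(np.isfinite(coeffs)) or abs(A4) < 1e-14 * max(1.0, np.abs(coeffs).max()):
        coeffs = coeffs[1:] if abs(A4) < 1e-14 else coeffs
    roots = np.roots(coeffs)
    dcoeffs = np.polyder(coeffs)
    poses = []
    for r in roots:
        if abs(r.imag) > 1e-6 * max(1.0, abs(r.real)):
            continue
        v = float(r.real)
        for _ in range(3):  # Newton polish (clustered roots lose precision)
            f = float(np.polyval(coeffs, v))
            df = float(np.polyval(dcoeffs, v))
            if abs(df) < 1e-14:
                break
            v -= f / df
        if v <= 0:
            continue
        s1sq = b * b / (1.0 + v * v - 2.0 * v * cos_beta)
        if s1sq <= 0:
            continue
        s1 = float(np.sqrt(s1sq))
        s3 = v * s1
        # u from the remaining law-of-cosines constraint (two branches),
        # validated against the third
        disc = cos_gamma**2 - 1.0 + c * c / s1sq
        if disc < 0:
            continue
        sq = float(np.sqrt(disc))
        for u in (cos_gamma + sq, cos_gamma - sq):
            if u <= 0:
                continue
            s2 = u * s1
            res = s2 * s2 + s3 * s3 - 2.0 * s2 * s3 * cos_alpha - a * a
            # loose check only: spurious branches are eliminated by the
            # caller (RANSAC inlier count or reprojection test)
            if abs(res) > 0.05 * max(a * a, 1e-12):
                continue
            Qc = np.vstack([s1 * j1, s2 * j2, s3 * j3])
            pose = _rigid_world_to_camera(Pw, Qc)
            if pose is not None:
                poses.append(pose)
    return poses


def _rigid_world_to_camera(Pw: np.ndarray, Qc: np.ndarray) -> CameraPose | None:
    """Proper rigid transform with Qc ~= R Pw + t (Kabsch on 3 points)."""
    cw = Pw.mean(axis=0)
    cc = Qc.mean(axis=0)
    H = (Pw - cw).T @ (Qc - cc)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    if not np.all(np.isfinite(R)):
        return None
    t = cc - R @ cw
    try:
        return CameraPose(R=R, C=-R.T @ t)
    except ValueError:
        return None


def refine_pose(
    pose: CameraPose, X: np.ndarray, uv: np.ndarray, intr: CameraIntrinsics
) -> CameraPose:
    """Nonlinear reprojection-error polish of a single pose."""
    x0 = np.concatenate([inverse_rodrigues(pose.R), pose.C])

    def resid(p):
        cand = CameraPose(R=rodrigues(p[:3]), C=p[3:])
        proj, _ = project_points(X, cand, intr)
        return (proj - uv).ravel()

    sol = optimize.least_squares(resid, x0, method="lm", max_nfev=200)
    return CameraPose(R=rodrigues(sol.x[:3]), C=sol.x[3:])


def pnp_ransac(
    X: np.ndarray,
    uv: np.ndarray,
    intr: CameraIntrinsics,
    threshold_px: float = 4.0,
    seed: int = 0,
    confidence: float = 0.999,
    max_iters: int = 500,
    min_iters: int = 30,
) -> tuple[CameraPose, np.ndarray]:
    """Pose from 2D-3D correspondences; returns (pose, inlier mask)."""
    X = np.asarray(X, dtype=float)
    uv = np.asarray(uv, dtype=float)
    n = X.shape[0]
    if n < 6:
        raise PnPError(f"need >= 6 correspondences, got {n}")
    xn, yn = intr.pixel_to_normalized(uv[:, 0], uv[:, 1])
    bearings = np.column_stack([xn, yn, np.ones_like(xn)])
    bearings /= np.linalg.norm(bearings, axis=1, keepdims=True)
    rng = np.random.default_rng(seed)
    best_pose = None
    best_inl = None
    best_count = 0
    n_iters = max_iters
    it = 0
    while it < max(n_iters, min_iters) and it < max_iters:
        it += 1
        idx = rng.choice(n, size=3, replace=False)
        for pose in p3p_solutions(X[idx], bearings[idx]):
            proj, z = project_points(X, pose, intr)
            err = np.linalg.norm(proj - uv, axis=1)
            inl = (err < threshold_px) & (z > 0)
            c = int(inl.sum())
            if c > best_count:
                best_count, best_inl, best_pose = c, inl, pose
                w = max(c / n, 1e-6)
                denom = np.log(max(1.0 - w**3, 1e-12))
                if denom < 0:
                    need = np.log(1.0 - confidence) / denom
                    n_iters = min(max_iters, int(np.ceil(min(need, max_iters))) + 1)
    if best_pose is None or best_count < 6:
        raise PnPError("RANSAC found no valid pose")
    pose = refine_pose(best_pose, X[best_inl], uv[best_inl], intr)
    proj, z = project_points(X, pose, intr)
    err = np.linalg.norm(proj - uv, axis=1)
    inl = (err < threshold_px) & (z > 0)
    if inl.sum() < 6:
        raise PnPError("refined pose lost its inliers")
    # second refinement pass on the (possibly larger) inlier set
    pose = refine_pose(pose, X[inl], uv[inl], intr)
    proj, z = project_points(X, pose, intr)
    err = np.linalg.norm(proj - uv, axis=1)
    inl = (err < threshold_px) & (z > 0)
    return pose, inl
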