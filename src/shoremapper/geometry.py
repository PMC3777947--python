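"""Camera model and multi-view geometry primitives.

Conventions used throughout the package:

* World frame: local ENU (x = east, y = north, z = up), metres (or arbitrary
  reconstruction units before geo-registration).
* Camera frame: x right, y down, z forward (optical axis).  A camera pose is
  the pair ``(R, C)`` with ``R`` the world-to-camera rotation and ``C`` the
  camera centre in world coordinates: ``x_cam = R @ (X - C)``.
* Pixel coordinates: origin at the centre of the top-left pixel, x rightward,
  y downward, 0-based.
* Radial distortion: two-parameter even polynomial on normalised coordinates,
  ``d = 1 + k1 r^2 + k2 r^4`` applied multiplicatively before the focal scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


# ---------------------------------------------------------------------------
# rotations
# ---------------------------------------------------------------------------

def rodrigues(rvec: np.ndarray) -> np.ndarray:
    """Rotation matrix from an axis-angle (Rodrigues) vector."""
    rvec = np.asarray(rvec, dtype=float)
    theta = np.linalg.norm(rvec)
    if theta < 1e-12:
        K = skew(rvec)
        return np.eye(3) + K  # first-order
    k = rvec / theta
    K = skew(k)
    return np.eye(3) + np.sin(theta) * K + (1.0 - np.cos(theta)) * (K @ K)


def inverse_rodrigues(R: np.ndarray) -> np.ndarray:
    """Axis-angle vector from a rotation matrix."""
    R = np.asarray(R, dtype=float)
    cos_theta = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    theta = np.arccos(cos_theta)
    if theta < 1e-12:
        return np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]]) / 2.0
    if np.pi - theta < 1e-6:
        # near pi: use the symmetric part
        A = (R + np.eye(3)) / 2.0
        axis = np.sqrt(np.maximum(np.diag(A), 0.0))
        # fix signs from off-diagonals
        i = int(np.argmax(axis))
        if axis[i] > 0:
            axis = A[i] / axis[i]
            axis = axis / np.linalg.norm(axis)
        return theta * axis
    axis = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    return theta / (2.0 * np.sin(theta)) * axis


def skew(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return np.array([[0.0, -v[2], v[1]], [v[2], 0.0, -v[0]], [-v[1], v[0], 0.0]])


def nearest_rotation(M: np.ndarray) -> np.ndarray:
    """Project a 3x3 matrix onto SO(3) (proper rotation) via SVD."""
    U, _, Vt = np.linalg.svd(np.asarray(M, dtype=float))
    R = U @ Vt
    if np.linalg.det(R) < 0:
        R = U @ np.diag([1.0, 1.0, -1.0]) @ Vt
    return R


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation (QR of a Gaussian matrix, sign-fixed)."""
    A = rng.standard_normal((3, 3))
    Q, Rm = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(Rm)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


# ---------------------------------------------------------------------------
# camera intrinsics / pose
# ---------------------------------------------------------------------------

@dataclass
class CameraIntrinsics:
    """Shared intrinsics of one camera body.

    focal : focal length in pixels (fx = fy, square pixels)
    cx, cy : principal point, pixels
    k1, k2 : even radial distortion coefficients
    width, height : sensor size in pixels
    """

    focal: float
    cx: float
    cy: float
    k1: float = 0.0
    k2: float = 0.0
    width: int = 640
    height: int = 480

    def __post_init__(self) -> None:
        if self.focal <= 0:
            raise ValueError("focal length must be positive")

    @property
    def K(self) -> np.ndarray:
        return np.array(
            [[self.focal, 0.0, self.cx], [0.0, self.focal, self.cy], [0.0, 0.0, 1.0]]
        )

    def distort(self, xn: np.ndarray, yn: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        r2 = xn * xn + yn * yn
        d = 1.0 + self.k1 * r2 + self.k2 * r2 * r2
        return xn * d, yn * d

    def undistort(self, xd: np.ndarray, yd: np.ndarray, iters: int = 8) -> tuple[np.ndarray, np.ndarray]:
        """Invert the radial model by fixed-point iteration."""
        xn, yn = np.array(xd, dtype=float, copy=True), np.array(yd, dtype=float, copy=True)
        for _ in range(iters):
            r2 = xn * xn + yn * yn
            d = 1.0 + self.k1 * r2 + self.k2 * r2 * r2
            xn = xd / d
            yn = yd / d
        return xn, yn

    def project_normalized(self, xn: np.ndarray, yn: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        xd, yd = self.distort(xn, yn)
        return self.focal * xd + self.cx, self.focal * yd + self.cy

    def pixel_to_normalized(self, u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        xd = (np.asarray(u, dtype=float) - self.cx) / self.focal
        yd = (np.asarray(v, dtype=float) - self.cy) / self.focal
        return self.undistort(xd, yd)

    def to_dict(self) -> dict:
        return {
            "focal": self.focal, "cx": self.cx, "cy": self.cy,
            "k1": self.k1, "k2": self.k2, "width": self.width, "height": self.height,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraIntrinsics":
        return cls(**d)


@dataclass
class CameraPose:
    """World-to-camera rotation and camera centre in world coordinates."""

    R: np.ndarray
    C: np.ndarray

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        err = np.abs(self.R @ self.R.T - np.eye(3)).max()
        if err > 1e-6 or np.linalg.det(self.R) < 0:
            raise ValueError("R must be a proper rotation matrix")

    @property
    def t(self) -> np.ndarray:
        """Translation of the [R|t] convention: x_cam = R X + t."""
        return -self.R @ self.C

    def transform(self, X: np.ndarray) -> np.ndarray:
        """World points (N,3) to camera frame."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.C) @ self.R.T

    def viewing_direction(self) -> np.ndarray:
        """Optical axis in world coordinates."""
        return self.R[2]

    def to_dict(self) -> dict:
        return {"R": self.R.tolist(), "C": self.C.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "CameraPose":
        return cls(np.array(d["R"]), np.array(d["C"]))


def project_points(
    X: np.ndarray, pose: CameraPose, intr: CameraIntrinsics
) -> tuple[np.ndarray, np.ndarray]:
    """Project world points into pixels.

    Returns (uv (N,2), depth (N,)).  Points behind the camera get a negative
    depth; callers filter on it.
    """
    Xc = pose.transform(X)
    z = Xc[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        xn = Xc[:, 0] / z
        yn = Xc[:, 1] / z
    u, v = intr.project_normalized(xn, yn)
    return np.column_stack([u, v]), z


def triangulate_linear(
    obs: list[tuple[CameraPose, CameraIntrinsics, float, float]]
) -> np.ndarray:
    """DLT triangulation of one point from >= 2 (pose, intrinsics, u, v) obs."""
    rows = []
    for pose, intr, u, v in obs:
        xn, yn = intr.pixel_to_normalized(u, v)
        P = np.hstack([pose.R, pose.t[:, None]])  # 3x4, normalized camera
        rows.append(float(xn) * P[2] - P[0])
        rows.append(float(yn) * P[2] - P[1])
    A = np.vstack(rows)
    _, _, Vt = np.linalg.svd(A)
    Xh = Vt[-1]
    if abs(Xh[3]) < 1e-15:
        return Xh[:3] * np.inf
    return Xh[:3] / Xh[3]


def triangulate_two_view(
    pose1: CameraPose, pose2: CameraPose,
    intr1: CameraIntrinsics, intr2: CameraIntrinsics,
    uv1: np.ndarray, uv2: np.ndarray,
) -> np.ndarray:
    """Vectorised DLT triangulation for N correspondences between two views."""
    uv1 = np.atleast_2d(uv1)
    uv2 = np.atleast_2d(uv2)
    x1, y1 = intr1.pixel_to_normalized(uv1[:, 0], uv1[:, 1])
    x2, y2 = intr2.pixel_to_normalized(uv2[:, 0], uv2[:, 1])
    P1 = np.hstack([pose1.R, pose1.t[:, None]])
    P2 = np.hstack([pose2.R, pose2.t[:, None]])
    n = uv1.shape[0]
    A = np.empty((n, 4, 4))
    A[:, 0] = x1[:, None] * P1[2] - P1[0]
    A[:, 1] = y1[:, None] * P1[2] - P1[1]
    A[:, 2] = x2[:, None] * P2[2] - P2[0]
    A[:, 3] = y2[:, None] * P2[2] - P2[1]
    _, _, Vt = np.linalg.svd(A)
    Xh = Vt[:, -1, :]
    w = Xh[:, 3:4]
    w = np.where(np.abs(w) < 1e-15, np.nan, w)
    return Xh[:, :3] / w


def triangulation_angles(X: np.ndarray, C1: np.ndarray, C2: np.ndarray) -> np.ndarray:
    """Angle (degrees) subtended at each point X by camera centres C1, C2."""
    X = np.atleast_2d(X)
    d1 = C1 - X
    d2 = C2 - X
    n1 = np.linalg.norm(d1, axis=1)
    n2 = np.linalg.norm(d2, axis=1)
    cosang = np.einsum("ij,ij->i", d1, d2) / np.maximum(n1 * n2, 1e-300)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
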