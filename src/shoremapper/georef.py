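"""Geo-registration of a scale-less reconstruction.

Absolute scale comes from tape-measured GCP triad edge lengths (local, precise);
absolute position/orientation comes from handheld-GPS GCP coordinates via
Horn's closed-form absolute orientation (global, ~metre grade); the vertical
datum is finally corrected by pinning the annotated waterline to the known
tide height.  Keeping the two information sources separate is what decouples
the map's local accuracy from its much poorer global (GPS-limited) accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .geodesy import GeodeticOrigin


@dataclass
class GCPRecord:
    """One checkerboard ground-control panel.

    Panels are placed in triads: equilateral triangles with a hand-measured
    (tape) edge length, giving scale information independent of GPS noise.
    ``recon_xyz`` is the panel position identified in the reconstruction frame
    (manual annotation in a real survey; ground truth in synthetic tests).
    """

    gcp_id: str
    triad_id: int
    lat_deg: float
    lon_deg: float
    alt_m: float
    edge_m: float
    recon_xyz: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.edge_m <= 0:
            raise ValueError("triad edge length must be positive")
        if self.recon_xyz is not None:
            self.recon_xyz = np.asarray(self.recon_xyz, dtype=float)


@dataclass
class SimilarityTransform:
    """x' = scale * R @ x + t  (reconstruction frame -> local ENU)."""

    scale: float
    R: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        self.R = np.asarray(self.R, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        if np.abs(self.R @ self.R.T - np.eye(3)).max() > 1e-6 or np.linalg.det(self.R) < 0:
            raise ValueError("R must be a proper rotation")

    def apply(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.scale * x @ self.R.T + self.t

    def inverse(self) -> "SimilarityTransform":
        Rinv = self.R.T
        return SimilarityTransform(1.0 / self.scale, Rinv, -Rinv @ self.t / self.scale)

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """self o other (apply ``other`` first)."""
        return SimilarityTransform(
            self.scale * other.scale,
            self.R @ other.R,
            self.scale * self.R @ other.t + self.t,
        )

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(1.0, np.eye(3), np.zeros(3))


@dataclass
class ResidualReport:
    """Global vs local accuracy of a geo-registered model.

    global_residual_m : mean 3D Euclidean distance between ENU-converted GPS
        GCP positions and the transformed reconstruction positions.
    global_residual_2d_m : same with horizontal components only.
    local_residual_m : mean absolute difference between tape-measured and
        reconstructed triad edge lengths.
    """

    global_residual_m: float
    global_residual_2d_m: float
    local_residual_m: float
    per_gcp_m: np.ndarray = field(default_factory=lambda: np.zeros(0))
    per_edge_m: np.ndarray = field(default_factory=lambda: np.zeros(0))
    scale: float = 1.0

    def to_dict(self) -> dict:
        return {
            "global_residual_m": self.global_residual_m,
            "global_residual_2d_m": self.global_residual_2d_m,
            "local_residual_m": self.local_residual_m,
            "scale": self.scale,
            "n_gcps": int(self.per_gcp_m.size),
        }


class DegenerateConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# scale from triads
# ---------------------------------------------------------------------------

def estimate_scale(gcps: list[GCPRecord]) -> float:
    """Mean over all triad edges of measured length / reconstructed length."""
    ratios = []
    by_triad: dict[int, list[GCPRecord]] = {}
    for g in gcps:
        by_triad.setdefault(g.triad_id, []).append(g)
    for triad_id, members in by_triad.items():
        annotated = [g for g in members if g.recon_xyz is not None]
        if len(annotated) != 3:
            continue
        for a, b in combinations(annotated, 2):
            d = float(np.linalg.norm(a.recon_xyz - b.recon_xyz))
            if d <= 0:
                raise ValueError(f"zero-length reconstructed edge in triad {triad_id}")
            ratios.append(a.edge_m / d)
    if not ratios:
        raise ValueError("no complete annotated triad available for scale estimation")
    return float(np.mean(ratios))


# ---------------------------------------------------------------------------
# Horn's absolute orientation
# ---------------------------------------------------------------------------

def horn_align(
    source: np.ndarray,
    target: np.ndarray,
    estimate_scale_flag: bool = False,
) -> tuple[SimilarityTransform, np.ndarray]:
    """Closed-form least-squares alignment target ~ s R source + t.

    Rotation from the quaternion eigen-solution of the cross-covariance
    (always a proper rotation, never a reflection); optional symmetric scale.
    Returns the transform and the per-point residual distances.
    """
    src = np.atleast_2d(np.asarray(source, dtype=float))
    dst = np.atleast_2d(np.asarray(target, dtype=float))
    if src.shape != dst.shape or src.shape[0] < 3:
        raise ValueError("need >= 3 corresponding 3D points")
    c_src = src.mean(axis=0)
    c_dst = dst.mean(axis=0)
    ps = src - c_src
    pd_ = dst - c_dst
    if np.linalg.matrix_rank(ps, tol=1e-9 * max(1.0, np.abs(ps).max())) < 2:
        raise DegenerateConfigurationError("source points are collinear or coincident")

    M = ps.T @ pd_
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    N = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    w, V = np.linalg.eigh(N)
    q = V[:, np.argmax(w)]  # (w, x, y, z)
    qw, qx, qy, qz = q
    R = np.array(
        [
            [1 - 2 * (qy * qy + qz * qz), 2 * (qx * qy - qw * qz), 2 * (qx * qz + qw * qy)],
            [2 * (qx * qy + qw * qz), 1 - 2 * (qx * qx + qz * qz), 2 * (qy * qz - qw * qx)],
            [2 * (qx * qz - qw * qy), 2 * (qy * qz + qw * qx), 1 - 2 * (qx * qx + qy * qy)],
        ]
    )
    if estimate_scale_flag:
        denom = np.sum(ps**2)
        s = float(np.sqrt(np.sum(pd_**2) / denom)) if denom > 0 else 1.0
    else:
        s = 1.0
    t = c_dst - s * R @ c_src
    tf = SimilarityTransform(s, R, t)
    residuals = np.linalg.norm(tf.apply(src) - dst, axis=1)
    return tf, residuals


# ---------------------------------------------------------------------------
# full geo-registration
# ---------------------------------------------------------------------------

def gcp_enu_positions(gcps: list[GCPRecord], origin: GeodeticOrigin) -> np.ndarray:
    return np.vstack(
        [origin.geodetic_to_enu(g.lat_deg, g.lon_deg, g.alt_m) for g in gcps]
    )


def residual_report(
    gcps: list[GCPRecord],
    transform: SimilarityTransform,
    origin: GeodeticOrigin,
) -> ResidualReport:
    annotated = [g for g in gcps if g.recon_xyz is not None]
    enu = gcp_enu_positions(annotated, origin)
    mapped = transform.apply(np.vstack([g.recon_xyz for g in annotated]))
    per_gcp = np.linalg.norm(mapped - enu, axis=1)
    per_gcp_2d = np.linalg.norm((mapped - enu)[:, :2], axis=1)
    edge_res = []
    by_triad: dict[int, list[int]] = {}
    for i, g in enumerate(annotated):
        by_triad.setdefault(g.triad_id, []).append(i)
    for members in by_triad.values():
        if len(members) != 3:
            continue
        for i, j in combinations(members, 2):
            rec_len = float(np.linalg.norm(mapped[i] - mapped[j]))
            edge_res.append(abs(annotated[i].edge_m - rec_len))
    return ResidualReport(
        global_residual_m=float(per_gcp.mean()),
        global_residual_2d_m=float(per_gcp_2d.mean()),
        local_residual_m=float(np.mean(edge_res)) if edge_res else np.nan,
        per_gcp_m=per_gcp,
        per_edge_m=np.asarray(edge_res),
        scale=transform.scale,
    )


def georegister(
    gcps: list[GCPRecord],
    origin: GeodeticOrigin,
) -> tuple[SimilarityTransform, ResidualReport]:
    """Two-stage geo-registration.

    1. Absolute scale from triad edge ratios (GPS plays no part).
    2. Horn alignment of the *scaled* reconstruction positions to the
       ENU-converted GPS coordinates with scale held fixed (rotation and
       translation only).

    Returns the reconstruction->ENU similarity and the residual report.
    """
    annotated = [g for g in gcps if g.recon_xyz is not None]
    if len(annotated) < 3:
        raise ValueError("need >= 3 annotated GCPs")
    s = estimate_scale(annotated)
    src = np.vstack([g.recon_xyz for g in annotated]) * s
    dst = gcp_enu_positions(annotated, origin)
    rigid, _ = horn_align(src, dst, estimate_scale_flag=False)
    full = SimilarityTransform(s, rigid.R, rigid.t)
    return full, residual_report(gcps, full, origin)


def adjust_vertical_datum(
    points_or_transform,
    waterline_enu: np.ndarray,
    datum_height_m: float,
):
    """Vertical shift pinning the mean waterline elevation to the tide datum.

    Accepts either an (N,3) point array (returns shifted copy + shift) or a
    SimilarityTransform (returns the transform composed with the shift +
    shift).  An empty waterline is a warning-level no-op (shift 0).
    """
    waterline_enu = np.asarray(waterline_enu, dtype=float)
    if waterline_enu.size == 0:
        import warnings

        warnings.warn("empty waterline: vertical datum left unchanged", stacklevel=2)
        shift = 0.0
    else:
        shift = datum_height_m - float(np.mean(waterline_enu[:, 2]))
    dz = np.array([0.0, 0.0, shift])
    if isinstance(points_or_transform, SimilarityTransform):
        tf = points_or_transform
        return SimilarityTransform(tf.scale, tf.R, tf.t + dz), shift
    pts = np.asarray(points_or_transform, dtype=float)
    return pts + dz, shift


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

def read_gcps_csv(path) -> list[GCPRecord]:
    df = pd.read_csv(path)
    return [
        GCPRecord(
            gcp_id=str(r["id"]), triad_id=int(r["triad_id"]), lat_deg=float(r["lat"]),
            lon_deg=float(r["lon"]), alt_m=float(r["alt"]), edge_m=float(r["edge_m"]),
        )
        for _, r in df.iterrows()
    ]


def attach_annotations(gcps: list[GCPRecord], annotations: pd.DataFrame) -> None:
    """Attach reconstruction-frame positions (columns: gcp_id, x, y, z)."""
    lookup = {
        str(r["gcp_id"]): np.array([r["x"], r["y"], r["z"]], dtype=float)
        for _, r in annotations.iterrows()
    }
    for g in gcps:
        if g.gcp_id in lookup:
            g.recon_xyz = lookup[g.gcp_id]


def read_annotations_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
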