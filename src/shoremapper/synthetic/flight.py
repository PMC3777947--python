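"""Kite flight planning over a synthetic scene.

The kite is walked in a zig-zag (serpentine) track along the shore at roughly
15-20 m altitude; the Picavet suspension keeps the camera near-nadir but not
exactly so.  Poses therefore follow serpentine strips with small random tilt
and translation jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

from ..geometry import CameraIntrinsics, CameraPose, rodrigues
from .scene import SceneModel

#: Nadir orientation: image x -> east, image y -> south, optical axis down.
NADIR_R = np.array([[1.0, 0.0, 0.0], [0.0, -1.0, 0.0], [0.0, 0.0, -1.0]])


def default_intrinsics(band: str = "colour") -> CameraIntrinsics:
    """Desk-scale camera bodies.

    At 15 m altitude a 450 px focal on a 640x480 sensor gives a ~21x16 m
    footprint (the regime of a 16 mm lens flown at kite altitude).  The two
    bodies differ slightly, as real consumer cameras do.
    """
    if band == "colour":
        return CameraIntrinsics(focal=450.0, cx=319.5, cy=239.5, k1=-0.06, k2=0.012,
                                width=640, height=480)
    if band == "nir":
        return CameraIntrinsics(focal=462.0, cx=320.3, cy=238.8, k1=-0.05, k2=0.010,
                                width=640, height=480)
    raise ValueError("band must be 'colour' or 'nir'")


@dataclass
class FlightPlan:
    """Ordered camera poses of one serpentine pass."""

    poses: list[CameraPose]
    altitude_range: tuple[float, float]
    overlap_fraction: float
    intrinsics: CameraIntrinsics
    band: str = "colour"

    def __len__(self) -> int:
        return len(self.poses)


def footprint_polygon(
    pose: CameraPose, intr: CameraIntrinsics, ground_z: float
) -> Polygon:
    """Image-corner rays intersected with the horizontal plane z = ground_z."""
    corners_px = np.array(
        [[0.0, 0.0], [intr.width - 1.0, 0.0], [intr.width - 1.0, intr.height - 1.0],
         [0.0, intr.height - 1.0]]
    )
    xn, yn = intr.pixel_to_normalized(corners_px[:, 0], corners_px[:, 1])
    dirs_cam = np.column_stack([xn, yn, np.ones_like(xn)])
    dirs_world = dirs_cam @ pose.R  # R^T @ d for each row
    tz = (ground_z - pose.C[2]) / dirs_world[:, 2]
    pts = pose.C[None, :] + tz[:, None] * dirs_world
    return Polygon(pts[:, :2])


def plan_flight(
    scene: SceneModel,
    altitude_m: float = 15.0,
    overlap: float = 0.6,
    seed: int = 0,
    intrinsics: CameraIntrinsics | None = None,
    band: str = "colour",
    n_strips: int = 2,
    n_images: int | None = None,
    jitter_rot_deg: float = 3.0,
    jitter_trans_m: float = 0.3,
    margin_m: float | None = None,
    start_offset_m: float = 0.0,
) -> FlightPlan:
    """Plan a serpentine kite track across the scene.

    ``overlap`` is the minimum footprint overlap fraction guaranteed between
    consecutive poses (0 disables the adjacency requirement).  The along-track
    step and strip spacing are derived from the nadir footprint at
    ``altitude_m``; jitter emulates kite motion.
    """
    if altitude_m <= 0:
        raise ValueError("altitude must be positive")
    if overlap >= 1.0:
        raise ValueError("overlap fraction must be < 1")
    intr = intrinsics if intrinsics is not None else default_intrinsics(band)
    rng = np.random.default_rng(seed)
    xmin, xmax, ymin, ymax = scene.extent

    # nadir footprint extents at the mean dry-terrain elevation
    ground_z = float(np.median(scene.heightfield))
    fp_x = (xmax - xmin, 2.0 * altitude_m * (intr.width / 2.0) / intr.focal)[1]
    fp_y = 2.0 * altitude_m * (intr.height / 2.0) / intr.focal
    # conservative steps: guarantee >= overlap even under jitter
    safety = 0.65 if overlap > 0 else 1.0
    step = max((1.0 - overlap) * fp_x * safety, 0.5)
    strip_gap = min((1.0 - overlap) * fp_y * safety, (ymax - ymin) / max(n_strips, 1))

    if margin_m is None:
        # keep every footprint inside the modelled extent (plus jitter room)
        margin_m = fp_x / 2.0 + 2.5
    x_lo, x_hi = xmin + margin_m, xmax - margin_m
    if x_hi <= x_lo:
        # scene narrower than a footprint: hover over the centre line
        x_lo = x_hi = 0.5 * (xmin + xmax)
    y_mid = 0.5 * (ymin + ymax)
    ys = y_mid + (np.arange(n_strips) - (n_strips - 1) / 2.0) * strip_gap

    waypoints = []
    if n_images is not None:
        # fit the requested count across the usable span (never exceed `step`)
        per_strip = int(np.ceil(n_images / n_strips))
        span = x_hi - x_lo - start_offset_m
        if per_strip > 1:
            step = min(step, span / (per_strip - 1))
        xs_all = (x_lo + start_offset_m + np.arange(per_strip) * step)
        xs_all = xs_all[xs_all <= x_hi + 1e-9][:per_strip]
    else:
        xs_all = np.arange(x_lo + start_offset_m, x_hi + 1e-9, step)
    for s in range(n_strips):
        xs = xs_all if s % 2 == 0 else xs_all[::-1]
        for x in xs:
            waypoints.append((float(x), float(ys[s])))
    if n_images is not None:
        waypoints = waypoints[:n_images]

    poses: list[CameraPose] = []
    alts = []
    for (x, y) in waypoints:
        dx, dy = rng.normal(0.0, jitter_trans_m, size=2)
        dz = rng.normal(0.0, jitter_trans_m / 2.0)
        gz = float(scene.elevation_at(x + dx, y + dy))
        C = np.array([x + dx, y + dy, gz + altitude_m + dz])
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        ang = np.radians(np.abs(rng.normal(0.0, jitter_rot_deg)))
        ang = min(ang, np.radians(5.0))
        R = rodrigues(axis * ang) @ NADIR_R
        poses.append(CameraPose(R=R, C=C))
        alts.append(altitude_m + dz)

    plan = FlightPlan(
        poses=poses,
        altitude_range=(float(np.min(alts)), float(np.max(alts))),
        overlap_fraction=overlap,
        intrinsics=intr,
        band=band,
    )
    if overlap > 0:
        achieved = consecutive_overlaps(plan, ground_z)
        if achieved.size and achieved.min() < overlap:
            raise RuntimeError(
                f"planned track violates the overlap requirement "
                f"(min {achieved.min():.2f} < {overlap:.2f})"
            )
    return plan


def consecutive_overlaps(plan: FlightPlan, ground_z: float) -> np.ndarray:
    """Footprint overlap fraction between each consecutive pose pair."""
    polys = [footprint_polygon(p, plan.intrinsics, ground_z) for p in plan.poses]
    out = []
    for a, b in zip(polys[:-1], polys[1:]):
        inter = a.intersection(b).area
        out.append(inter / min(a.area, b.area))
    return np.asarray(out)
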