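"""Synthetic intertidal shore scenes with known ground truth.

A scene is a smooth heightfield (gentle cross-shore ramp + band-limited noise
octaves + carved rock-pool depressions) over a plan-view rectangle, with a
contiguous patchwork of surface-coverage classes (rock, sand, macroalgae,
cunjevoi) whose reflectance spectra carry the chlorophyll red-edge signal that
drives NDVI.  Cells below the tidal water datum are water.

Scene coordinates are a local ENU frame (x east, y north, z up, metres)
anchored at the scene centroid; a configurable geodetic origin ties the frame
to latitude/longitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from ..geodesy import DEFAULT_ORIGIN, GeodeticOrigin
from ..georef import GCPRecord
from ..spectra import Spectrum

#: Surface coverage classes of a temperate intertidal rocky shore.
CLASS_NAMES = (
    "dry_rock",
    "wet_rock",
    "sand",
    "macroalgae_green",
    "macroalgae_red",
    "macroalgae_brown",
    "cunjevoi",
    "water",
)

WATER = CLASS_NAMES.index("water")


@dataclass(frozen=True)
class SceneClass:
    name: str
    index: int


def _chlorophyll_spectrum(
    grid: np.ndarray, green_bump: float, red_trough: float, nir_plateau: float,
    edge_nm: float = 706.0, edge_width_nm: float = 14.0,
) -> np.ndarray:
    """Reflectance with a green reflectance bump, red absorption trough and
    a sigmoidal red edge onto a near-infrared plateau (live algae shape)."""
    base = red_trough + (green_bump - red_trough) * np.exp(-0.5 * ((grid - 550.0) / 40.0) ** 2)
    edge = 1.0 / (1.0 + np.exp(-(grid - edge_nm) / edge_width_nm))
    return base * (1.0 - edge) + nir_plateau * edge


def default_class_spectra(grid_nm: np.ndarray | None = None) -> dict[str, Spectrum]:
    """Reflectance spectra for the coverage classes (400-800 nm).

    Live macroalgae use the chlorophyll red-edge shape; rock and sand are
    spectrally bland; water absorbs strongly in the near infrared.
    """
    if grid_nm is None:
        grid_nm = np.arange(400.0, 801.0, 5.0)
    g = np.asarray(grid_nm, dtype=float)
    ramp = (g - g[0]) / (g[-1] - g[0])
    spectra = {
        "dry_rock": 0.26 + 0.04 * ramp,
        "wet_rock": 0.11 + 0.02 * ramp,
        "sand": 0.30 + 0.08 * ramp,
        "macroalgae_green": _chlorophyll_spectrum(g, 0.13, 0.05, 0.44),
        "macroalgae_red": _chlorophyll_spectrum(g, 0.07, 0.055, 0.30),
        "macroalgae_brown": _chlorophyll_spectrum(g, 0.10, 0.05, 0.37),
        "cunjevoi": 0.13 + 0.05 * 1.0 / (1.0 + np.exp(-(g - 700.0) / 25.0)),
        "water": 0.048 * (1.0 - 1.0 / (1.0 + np.exp(-(g - 640.0) / 22.0))) + 0.002,
    }
    return {k: Spectrum(g, np.clip(v, 0.0, 1.0)) for k, v in spectra.items()}


@dataclass
class SceneModel:
    """Heightfield terrain + coverage classes + class reflectance spectra."""

    heightfield: np.ndarray          # (ny, nx) elevation, metres
    coverage: np.ndarray             # (ny, nx) int class labels
    class_spectra: dict[str, Spectrum]
    cell_m: float
    extent: tuple[float, float, float, float]   # xmin, xmax, ymin, ymax (ENU)
    water_datum: float
    origin: GeodeticOrigin = field(default_factory=lambda: DEFAULT_ORIGIN)
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.heightfield)):
            raise ValueError("heightfield must be finite")
        for name, s in self.class_spectra.items():
            if s.reflectance.min() < 0 or s.reflectance.max() > 1:
                raise ValueError(f"class spectrum {name} outside [0,1]")

    # -- coordinate mapping ------------------------------------------------
    def _grid_coords(self, x, y):
        xmin, _, ymin, _ = self.extent
        return (np.asarray(y, dtype=float) - ymin) / self.cell_m, (
            np.asarray(x, dtype=float) - xmin
        ) / self.cell_m

    def elevation_at(self, x, y) -> np.ndarray:
        """Bilinear heightfield lookup (edge-clamped)."""
        r, c = self._grid_coords(x, y)
        scalar = np.ndim(r) == 0
        out = ndimage.map_coordinates(
            self.heightfield, [np.atleast_1d(r), np.atleast_1d(c)], order=1, mode="nearest"
        )
        return out[0] if scalar else out

    def class_at(self, x, y) -> np.ndarray:
        r, c = self._grid_coords(x, y)
        r = np.clip(np.rint(r).astype(int), 0, self.coverage.shape[0] - 1)
        c = np.clip(np.rint(c).astype(int), 0, self.coverage.shape[1] - 1)
        return self.coverage[r, c]

    def slope_bound(self) -> float:
        gy, gx = np.gradient(self.heightfield, self.cell_m)
        return float(np.hypot(gx, gy).max())

    @property
    def size_m(self) -> tuple[float, float]:
        xmin, xmax, ymin, ymax = self.extent
        return xmax - xmin, ymax - ymin


def generate_scene(
    size_m: tuple[float, float] = (68.0, 28.0),
    n_classes: int = 7,
    seed: int = 0,
    cell_m: float = 0.05,
    water_datum: float = 0.16,
    relief_m: float = 0.35,
    shore_rise_m: tuple[float, float] = (-0.45, 1.9),
    n_pools: int = 12,
    class_patch_m: float = 5.0,
    flat_reflectance: float | None = None,
    origin: GeodeticOrigin = DEFAULT_ORIGIN,
) -> SceneModel:
    """Generate a synthetic intertidal shore.

    The heightfield is a cross-shore ramp (seaward edge below the tidal datum
    so a waterline exists) plus smoothed-noise octaves and carved rock-pool
    depressions.  Coverage classes form contiguous patches of scale
    ``class_patch_m``; with ``n_classes=1`` and ``flat_reflectance`` set, the
    whole scene has one flat spectrum (degenerate test case).

    Deterministic: the same arguments and seed give a bit-identical scene.
    """
    Lx, Ly = float(size_m[0]), float(size_m[1])
    if Lx <= 0 or Ly <= 0:
        raise ValueError("scene extent must have positive area")
    if not 1 <= n_classes <= len(CLASS_NAMES) - 1:
        raise ValueError(f"n_classes must be in [1, {len(CLASS_NAMES) - 1}]")
    rng = np.random.default_rng(seed)
    nx = int(round(Lx / cell_m)) + 1
    ny = int(round(Ly / cell_m)) + 1
    extent = (-Lx / 2.0, Lx / 2.0, -Ly / 2.0, Ly / 2.0)

    # cross-shore ramp: seaward (south, low y) below the datum
    yy = np.linspace(0.0, 1.0, ny)[:, None]
    z = shore_rise_m[0] + (shore_rise_m[1] - shore_rise_m[0]) * yy
    z = np.broadcast_to(z, (ny, nx)).copy()

    # band-limited noise octaves
    for scale_m, amp in ((8.0, 1.0), (3.0, 0.45), (1.2, 0.2)):
        sigma = scale_m / cell_m / 2.0
        noise = ndimage.gaussian_filter(rng.standard_normal((ny, nx)), sigma)
        sd = noise.std()
        if sd > 0:
            z += relief_m * amp * noise / sd

    # carved rock-pool depressions
    xg = np.arange(nx) * cell_m
    yg = np.arange(ny) * cell_m
    XX, YY = np.meshgrid(xg, yg)
    for _ in range(n_pools):
        cx = rng.uniform(0.05 * Lx, 0.95 * Lx)
        cy = rng.uniform(0.2 * Ly, 0.9 * Ly)
        radius = rng.uniform(0.6, 2.2)
        depth = rng.uniform(0.15, 0.5)
        r2 = ((XX - cx) ** 2 + (YY - cy) ** 2) / radius**2
        z -= depth * np.exp(-0.5 * r2)

    # coverage: argmax of smoothed random fields -> contiguous patches
    all_spectra = default_class_spectra()
    if flat_reflectance is not None:
        names = ["dry_rock"]
        grid = all_spectra["dry_rock"].wavelength_nm
        spectra = {
            "dry_rock": Spectrum(grid, np.full_like(grid, flat_reflectance)),
            "water": Spectrum(grid, np.full_like(grid, flat_reflectance)),
        }
        coverage = np.zeros((ny, nx), dtype=np.int8)
    else:
        names = [n for n in CLASS_NAMES if n != "water"][:n_classes]
        spectra = {n: all_spectra[n] for n in names}
        spectra["water"] = all_spectra["water"]
        sigma_c = class_patch_m / cell_m / 2.0
        fields = np.stack(
            [ndimage.gaussian_filter(rng.standard_normal((ny, nx)), sigma_c) for _ in names]
        )
        # bias: algae favour the low shore, dry rock the high shore
        y01 = np.broadcast_to(yy, (ny, nx))
        for i, n in enumerate(names):
            if n.startswith("macroalgae"):
                fields[i] += 0.35 * (0.55 - y01) * fields.std()
            if n == "dry_rock":
                fields[i] += 0.35 * (y01 - 0.45) * fields.std()
        winner = np.argmax(fields, axis=0)
        coverage = np.array([CLASS_NAMES.index(n) for n in names], dtype=np.int8)[winner]

    # water cells are exactly the cells below the datum
    coverage = np.where(z < water_datum, np.int8(WATER), coverage)

    return SceneModel(
        heightfield=z,
        coverage=coverage,
        class_spectra=spectra,
        cell_m=cell_m,
        extent=extent,
        water_datum=water_datum,
        origin=origin,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# ground control point triads
# ---------------------------------------------------------------------------

def _tangent_frame(scene: SceneModel, x: float, y: float, probe_m: float = 0.4):
    """Orthonormal (u, v) basis of the terrain tangent plane at (x, y)."""
    zx = (scene.elevation_at(x + probe_m, y) - scene.elevation_at(x - probe_m, y)) / (2 * probe_m)
    zy = (scene.elevation_at(x, y + probe_m) - scene.elevation_at(x, y - probe_m)) / (2 * probe_m)
    n = np.array([-float(zx), -float(zy), 1.0])
    n /= np.linalg.norm(n)
    u = np.cross(np.array([0.0, 1.0, 0.0]), n)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def place_gcps(
    scene: SceneModel,
    n_triads: int = 3,
    edge_m: float = 2.0,
    gps_noise_sd_m: float = 1.2,
    seed: int = 0,
    min_clearance_m: float = 0.25,
) -> tuple[list[GCPRecord], np.ndarray]:
    """Place equilateral GCP triads on dry ground.

    Each triad is an exact equilateral triangle of 3D side ``edge_m`` lying in
    the local terrain tangent plane (flat panels on locally flat rock, tape-
    measured edges).  Geodetic coordinates get handheld-GPS noise of standard
    deviation ``gps_noise_sd_m`` per axis (1.5x vertically); the noise-free
    ENU positions are returned separately as ground truth.

    Returns ``(records, true_enu)`` with ``true_enu`` of shape (3*n_triads, 3).
    """
    if n_triads <= 0:
        raise ValueError("n_triads must be positive")
    rng = np.random.default_rng(seed)
    xmin, xmax, ymin, ymax = scene.extent
    margin = 2.0 * edge_m
    records: list[GCPRecord] = []
    true_positions = []
    placed = []
    attempts = 0
    while len(placed) < n_triads:
        attempts += 1
        if attempts > 3000:
            raise RuntimeError("could not place GCP triads on dry ground within the extent")
        cx = rng.uniform(xmin + margin, xmax - margin)
        cy = rng.uniform(ymin + margin, ymax - margin)
        # dry, above the datum with clearance, away from other triads
        probe_x = cx + np.array([0.0, edge_m, -edge_m, 0.0, 0.0])
        probe_y = cy + np.array([0.0, 0.0, 0.0, edge_m, -edge_m])
        zs = scene.elevation_at(probe_x, probe_y)
        if np.min(zs) < scene.water_datum + min_clearance_m:
            continue
        if any(np.hypot(cx - px, cy - py) < 4.0 * edge_m for px, py in placed):
            continue
        placed.append((cx, cy))

    for t, (cx, cy) in enumerate(placed):
        u, v = _tangent_frame(scene, cx, cy)
        centre = np.array([cx, cy, float(scene.elevation_at(cx, cy))])
        r = edge_m / np.sqrt(3.0)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        for k in range(3):
            ang = phase + 2.0 * np.pi * k / 3.0
            p = centre + r * (np.cos(ang) * u + np.sin(ang) * v)
            true_positions.append(p)
            noisy = p + np.array(
                [
                    rng.normal(0.0, gps_noise_sd_m),
                    rng.normal(0.0, gps_noise_sd_m),
                    rng.normal(0.0, 1.5 * gps_noise_sd_m),
                ]
            )
            lat, lon, alt = scene.origin.enu_to_geodetic(noisy)
            records.append(
                GCPRecord(
                    gcp_id=f"gcp_{t}_{k}",
                    triad_id=t,
                    lat_deg=float(lat),
                    lon_deg=float(lon),
                    alt_m=float(alt),
                    edge_m=edge_m,
                )
            )
    return records, np.asarray(true_positions)


# ---------------------------------------------------------------------------
# waterline
# ---------------------------------------------------------------------------

class DrySceneError(ValueError):
    """Raised when a scene has no cells below the water datum."""


def extract_waterline(scene: SceneModel, max_points: int = 2000) -> np.ndarray:
    """Points (N,3) on the water-datum elevation contour of the heightfield.

    Emulates manually outlining the visible waterline: the contour of the
    terrain at the datum elevation, with z evaluated by bilinear lookup at the
    contour vertices (so residuals are bounded by grid interpolation error).
    """
    if not np.any(scene.heightfield < scene.water_datum):
        raise DrySceneError("scene is fully dry: no waterline to extract")
    contours = measure.find_contours(scene.heightfield, scene.water_datum)
    if not contours:
        raise DrySceneError("no waterline contour found at the datum elevation")
    xmin, _, ymin, _ = scene.extent
    pts = []
    for cont in contours:
        x = xmin + cont[:, 1] * scene.cell_m
        y = ymin + cont[:, 0] * scene.cell_m
        z = scene.elevation_at(x, y)
        pts.append(np.column_stack([x, y, z]))
    out = np.vstack(pts)
    if out.shape[0] > max_points:
        step = int(np.ceil(out.shape[0] / max_points))
        out = out[::step]
    return out


def gcps_to_csv(records: list[GCPRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "id": r.gcp_id, "triad_id": r.triad_id, "lat": r.lat_deg,
                "lon": r.lon_deg, "alt": r.alt_m, "edge_m": r.edge_m,
            }
            for r in records
        ]
    ).to_csv(path, index=False)
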