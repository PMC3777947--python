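"""View selection, blending, orthomosaics, white balance and NDVI.

Every terrain face is textured from the four nearest images that actually
see it (projection in bounds, front-facing, unoccluded per a z-buffer test),
blended with fixed inverse-rank weights.  Orthographic top-down re-rendering
of the textured surface produces colour and near-infrared mosaics on a
common grid, from which white-balanced NDVI is computed per cell:

    NDVI = (g_nir * NIR - g_red * R) / (g_nir * NIR + g_red * R)

The white-balance gains are defined by the property that a spectrally flat
(Spectralon-like) surface maps to equal balanced values in both channels —
hence NDVI exactly 0 — after accounting for the different exposure times of
the two camera bodies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import project_points
from .sfm.model import ReconstructionModel
from .terrain import NODATA, RasterGrid, TerrainMesh

RANK_WEIGHTS = np.array([4.0, 3.0, 2.0, 1.0])


@dataclass
class TextureAssignment:
    """Per-face ranked source images and blend weights, per band."""

    face_ids: np.ndarray                       # (F,) indices into the mesh
    images: dict[str, np.ndarray]              # band -> (F, 4) int ids, -1 = none
    weights: dict[str, np.ndarray]             # band -> (F, 4) float, rows sum to 1
    image_ids: list[str]                       # global image index -> image id

    def n_sources(self, band: str) -> np.ndarray:
        return (self.images[band] >= 0).sum(axis=1)


@dataclass
class OrthoMosaic:
    """Geo-referenced raster stack: R, G, B (colour body), NIR (NIR body)."""

    bands: dict[str, RasterGrid]               # "R","G","B","NIR"
    source_count: dict[str, RasterGrid] = field(default_factory=dict)

    @property
    def cell_m(self) -> float:
        return next(iter(self.bands.values())).cell_m


@dataclass
class NDVIRaster:
    grid: RasterGrid
    gains: tuple[float, float]                 # (g_red, g_nir)
    exposures_s: tuple[float, float]           # (t_colour, t_nir)


@dataclass
class PatchStats:
    label: str
    centre: tuple[float, float]                # raster (col, row)
    size_px: int
    mean: float
    sd: float


# ---------------------------------------------------------------------------
# visibility and view selection
# ---------------------------------------------------------------------------

def _zbuffer_visibility(
    centres: np.ndarray,
    uv: np.ndarray,
    depth: np.ndarray,
    in_bounds: np.ndarray,
    width: int,
    height: int,
    bin_px: int = 8,
    tol_m: float = 0.2,
) -> np.ndarray:
    """Point-splat z-buffer: a face centre is visible if no other centre
    projects into its bin at a meaningfully smaller depth."""
    nx = int(np.ceil(width / bin_px))
    ny = int(np.ceil(height / bin_px))
    zbuf = np.full(nx * ny, np.inf)
    iu = np.clip((uv[:, 0] / bin_px).astype(int), 0, nx - 1)
    iv = np.clip((uv[:, 1] / bin_px).astype(int), 0, ny - 1)
    flat = iv * nx + iu
    np.minimum.at(zbuf, flat[in_bounds], depth[in_bounds])
    vis = in_bounds & (depth <= zbuf[flat] + tol_m)
    return vis


def select_views(
    mesh: TerrainMesh,
    model: ReconstructionModel,
    bands: tuple[str, ...] = ("colour", "nir"),
    max_views: int = 4,
    zbuffer_bin_px: int = 8,
    zbuffer_tol_m: float = 0.2,
) -> TextureAssignment:
    """Assign the best (minimum face-to-camera distance) <= 4 images per band
    to every valid mesh face.

    Ties on distance break deterministically towards the lower image index
    (stable sort).  Faces seen by no image in a band get an empty list there.
    """
    centres = mesh.face_centres
    normals_enu = np.column_stack(
        [mesh.normals_ned[:, 1], mesh.normals_ned[:, 0], -mesh.normals_ned[:, 2]]
    )
    F = centres.shape[0]
    image_ids = sorted(model.poses)
    assignment_images: dict[str, np.ndarray] = {}
    assignment_weights: dict[str, np.ndarray] = {}
    for band in bands:
        band_imgs = [i for i in image_ids if model.image_bands[i] == band]
        if not band_imgs:
            assignment_images[band] = np.full((F, max_views), -1, dtype=int)
            assignment_weights[band] = np.zeros((F, max_views))
            continue
        dists = np.full((F, len(band_imgs)), np.inf, dtype=np.float64)
        for k, img in enumerate(band_imgs):
            pose = model.poses[img]
            intr = model.intrinsics[band]
            uv, z = project_points(centres, pose, intr)
            inb = (
                (z > 0)
                & (uv[:, 0] >= 0) & (uv[:, 0] <= intr.width - 1)
                & (uv[:, 1] >= 0) & (uv[:, 1] <= intr.height - 1)
            )
            front = np.einsum("ij,ij->i", normals_enu, pose.C[None, :] - centres) > 0
            d = np.linalg.norm(centres - pose.C, axis=1)
            vis = _zbuffer_visibility(centres, uv, d, inb & front,
                                      intr.width, intr.height,
                                      bin_px=zbuffer_bin_px, tol_m=zbuffer_tol_m)
            dists[vis, k] = d[vis]
        order = np.argsort(dists, axis=1, kind="stable")[:, :max_views]
        chosen_d = np.take_along_axis(dists, order, axis=1)
        ids = np.asarray([image_ids.index(band_imgs[k]) for k in range(len(band_imgs))])
        chosen = ids[order]
        chosen[~np.isfinite(chosen_d)] = -1
        if chosen.shape[1] < max_views:  # fewer images than slots
            pad = max_views - chosen.shape[1]
            chosen = np.pad(chosen, ((0, 0), (0, pad)), constant_values=-1)
        w = np.where(chosen >= 0, RANK_WEIGHTS[None, : max_views], 0.0)
        wsum = w.sum(axis=1, keepdims=True)
        w = np.divide(w, wsum, out=np.zeros_like(w), where=wsum > 0)
        assignment_images[band] = chosen
        assignment_weights[band] = w
    return TextureAssignment(
        face_ids=np.arange(F), images=assignment_images,
        weights=assignment_weights, image_ids=image_ids,
    )


# ---------------------------------------------------------------------------
# blending
# ---------------------------------------------------------------------------

def _bilinear_sample(img: np.ndarray, uv: np.ndarray) -> np.ndarray:
    """Sample (H,W) or (H,W,C) image at float pixel coords; edge-clamped."""
    coords = [uv[:, 1], uv[:, 0]]
    if img.ndim == 2:
        return ndimage.map_coordinates(img, coords, order=1, mode="nearest")
    return np.stack(
        [ndimage.map_coordinates(img[..., c], coords, order=1, mode="nearest")
         for c in range(img.shape[2])],
        axis=1,
    )


def blend_points(
    points: np.ndarray,
    face_idx: np.ndarray,
    assignment: TextureAssignment,
    images: dict[str, np.ndarray],
    model: ReconstructionModel,
    band: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Blend the assigned images of each point's face at the point's
    projection.  Returns (values, n_sources); values are NaN where no
    assigned image covers the point.

    The blend is a convex combination, so values are bounded by the
    contributing samples.
    """
    n = points.shape[0]
    nch = 3 if band == "colour" else 1
    acc = np.zeros((n, nch))
    wacc = np.zeros(n)
    count = np.zeros(n, dtype=int)
    ids = assignment.images[band][face_idx]           # (n, 4)
    ws = assignment.weights[band][face_idx]
    intr = model.intrinsics.get(band)
    for r in range(ids.shape[1]):
        col = ids[:, r]
        for gid in np.unique(col[col >= 0]):
            img_id = assignment.image_ids[gid]
            sel = col == gid
            uv, z = project_points(points[sel], model.poses[img_id], intr)
            ok = (
                (z > 0)
                & (uv[:, 0] >= 0) & (uv[:, 0] <= intr.width - 1)
                & (uv[:, 1] >= 0) & (uv[:, 1] <= intr.height - 1)
            )
            pix = np.asarray(images[img_id], dtype=float)
            vals = _bilinear_sample(pix, uv[ok])
            if vals.ndim == 1:
                vals = vals[:, None]
            sel_idx = np.flatnonzero(sel)[ok]
            w = ws[sel_idx, r]
            acc[sel_idx] += w[:, None] * vals
            wacc[sel_idx] += w
            count[sel_idx] += 1
    out = np.divide(acc, wacc[:, None], out=np.full_like(acc, np.nan),
                    where=wacc[:, None] > 0)
    return out, count


def blend_face(
    face_id: int,
    assignment: TextureAssignment,
    images: dict[str, np.ndarray],
    model: ReconstructionModel,
    mesh: TerrainMesh,
    band: str = "colour",
    points: np.ndarray | None = None,
) -> np.ndarray:
    """Texel values for one face (defaults to its centroid)."""
    if points is None:
        points = mesh.face_centres[face_id][None, :]
    vals, _ = blend_points(points, np.full(points.shape[0], face_id), assignment,
                           images, model, band)
    return vals


# ---------------------------------------------------------------------------
# orthomosaic
# ---------------------------------------------------------------------------

def render_orthomosaic(
    mesh: TerrainMesh,
    assignment: TextureAssignment,
    images: dict[str, np.ndarray],
    model: ReconstructionModel,
    cell_m: float,
    bounds: tuple[float, float, float, float] | None = None,
) -> OrthoMosaic:
    """Top-down orthographic re-render of the textured terrain.

    Colour and NIR coverage may differ: faces unseen by one band are nodata
    in that band only.
    """
    if all((assignment.images[b] < 0).all() for b in assignment.images):
        raise ValueError("texture assignment is empty")
    from .terrain import rasterize_terrain

    rasters = rasterize_terrain(mesh, cell_m, bounds=bounds)
    elev = rasters["elevation"]
    mask = elev.defined_mask()
    XX, YY = elev.cell_centres()
    pts = np.column_stack([XX[mask], YY[mask], elev.data[mask]])
    simplex = mesh._tri.find_simplex(pts[:, :2])

    bands_out: dict[str, RasterGrid] = {}
    counts: dict[str, RasterGrid] = {}
    band_channels = {"colour": ("R", "G", "B"), "nir": ("NIR",)}
    for band, channels in band_channels.items():
        if band not in assignment.images:
            continue
        vals, count = blend_points(pts, simplex, assignment, images, model, band)
        for c_i, ch in enumerate(channels):
            grid = np.full(elev.shape, NODATA)
            v = vals[:, c_i]
            flat = np.full(mask.sum(), NODATA)
            good = ~np.isnan(v)
            flat[good] = v[good]
            grid[mask] = flat
            bands_out[ch] = RasterGrid(grid, elev.origin, cell_m, name=ch)
        cgrid = np.zeros(elev.shape)
        cgrid[mask] = count
        counts[band] = RasterGrid(cgrid, elev.origin, cell_m, nodata=0, name=f"count_{band}")
    return OrthoMosaic(bands=bands_out, source_count=counts)


# ---------------------------------------------------------------------------
# white balance and NDVI
# ---------------------------------------------------------------------------

def white_balance_gains(
    spectralon_values: dict[str, float],
    exposure_times: dict[str, float],
) -> tuple[float, float]:
    """Gains (g_red, g_nir) normalising the two channels to a common scale.

    ``spectralon_values`` are the mean red / nir channel values of a
    Spectralon white target imaged by each camera at its survey exposure.
    With ``t_ref`` the colour body's exposure, ``g_c = t_ref / W_c``: the
    balanced Spectralon response is then identical in both channels, which
    folds in the exposure-time ratio between the cameras.  Defining property
    (unit-tested): a spectrally flat surface gets NDVI exactly 0.
    """
    W_red = spectralon_values.get("red")
    W_nir = spectralon_values.get("nir")
    t_col = exposure_times.get("colour")
    t_nir = exposure_times.get("nir")
    for name, v in (("red", W_red), ("nir", W_nir),
                    ("t_colour", t_col), ("t_nir", t_nir)):
        if v is None or v <= 0:
            raise ValueError(f"white balance input {name!r} must be positive")
    t_ref = t_col
    return t_ref / W_red, t_ref / W_nir


def compute_ndvi(
    mosaic: OrthoMosaic,
    gains: tuple[float, float],
    exposures_s: tuple[float, float] = (np.nan, np.nan),
    eps: float = 1e-12,
) -> NDVIRaster:
    """Per-cell NDVI of the white-balanced red and near-infrared mosaics."""
    R = mosaic.bands["R"]
    N = mosaic.bands["NIR"]
    if R.data.shape != N.data.shape or R.origin != N.origin:
        raise ValueError("R and NIR bands must share a grid")
    g_red, g_nir = gains
    r = g_red * R.data
    n = g_nir * N.data
    defined = R.defined_mask() & N.defined_mask()
    denom = n + r
    defined &= np.abs(denom) > eps
    out = np.full(R.data.shape, NODATA)
    out[defined] = (n[defined] - r[defined]) / denom[defined]
    return NDVIRaster(
        grid=RasterGrid(out, R.origin, R.cell_m, name="ndvi"),
        gains=gains, exposures_s=exposures_s,
    )


# ---------------------------------------------------------------------------
# patch validation statistics
# ---------------------------------------------------------------------------

def patch_statistics(
    raster: NDVIRaster,
    patches: pd.DataFrame,
    predicted: dict[str, float] | None = None,
    size_px: int = 15,
) -> tuple[list[PatchStats], pd.DataFrame]:
    """Mean/sd NDVI of labelled square patches + per-label aggregation.

    ``patches`` columns: label, cx, cy (raster column/row of patch centre).
    Patches overlapping nodata are excluded with a warning.  ``predicted``
    (label -> NDVI from reflectance spectra and camera response curves)
    is joined into the per-label table for predicted-vs-measured comparison.
    """
    half = size_px // 2
    data = raster.grid.data
    stats: list[PatchStats] = []
    for _, row in patches.iterrows():
        cx, cy = int(round(row["cx"])), int(round(row["cy"]))
        y0, y1 = cy - half, cy + half + 1
        x0, x1 = cx - half, cx + half + 1
        if y0 < 0 or x0 < 0 or y1 > data.shape[0] or x1 > data.shape[1]:
            warnings.warn(f"patch at ({cx},{cy}) outside raster: excluded", stacklevel=2)
            continue
        block = data[y0:y1, x0:x1]
        if np.any(block == raster.grid.nodata):
            warnings.warn(f"patch at ({cx},{cy}) overlaps nodata: excluded", stacklevel=2)
            continue
        stats.append(PatchStats(
            label=str(row["label"]), centre=(float(cx), float(cy)), size_px=size_px,
            mean=float(block.mean()), sd=float(block.std()),
        ))
    rows = []
    for label in sorted({s.label for s in stats}):
        sel = [s for s in stats if s.label == label]
        means = np.array([s.mean for s in sel])
        row = {
            "label": label,
            "n_patches": len(sel),
            "measured_mean": float(means.mean()),
            "measured_sd": float(means.std()),
        }
        if predicted is not None and label in predicted:
            row["predicted"] = predicted[label]
            row["difference"] = row["measured_mean"] - predicted[label]
        rows.append(row)
    return stats, pd.DataFrame(rows)
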