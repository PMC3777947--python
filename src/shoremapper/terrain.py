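"""2.5D terrain surface and elevation / slope / aspect products.

The geo-referenced dense pointcloud is triangulated in plan view (Delaunay)
with vertex elevations lifted, giving a single-valued terrain surface.
Per-face slope and aspect derive from the face's unit normal expressed in
north-east-down components ``n = (n_N, n_E, n_D)`` (oriented upward,
``n_D < 0``):

    slope  = arccos(-n_D)                 in [0, 90) degrees
    aspect = atan2(n_E, n_N) mod 360      clockwise from north (downslope
                                          direction); undefined for
                                          horizontal faces

These are the standard GIS normal-vector forms.  Rasters are produced by
barycentric interpolation of elevation and by the covering face's slope and
aspect, with nodata outside the triangulated coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, QhullError

NODATA = -9999.0


class CollinearPointsError(ValueError):
    pass


@dataclass
class RasterGrid:
    """Geo-referenced single-band raster.

    ``origin`` is the world (ENU) coordinate of the *centre* of cell (0, 0);
    rows increase northward (y), columns eastward (x).
    """

    data: np.ndarray
    origin: tuple[float, float]
    cell_m: float
    nodata: float = NODATA
    name: str = ""

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.data.shape
        x = self.origin[0] + np.arange(nx) * self.cell_m
        y = self.origin[1] + np.arange(ny) * self.cell_m
        return np.meshgrid(x, y)

    def defined_mask(self) -> np.ndarray:
        return self.data != self.nodata

    def defined_values(self) -> np.ndarray:
        return self.data[self.defined_mask()]


@dataclass
class TerrainMesh:
    """Triangulated 2.5D surface with per-face unit normals (NED)."""

    vertices: np.ndarray            # (N, 3) ENU metres
    faces: np.ndarray               # (F, 3) vertex indices
    normals_ned: np.ndarray         # (F, 3): n_N, n_E, n_D, unit, n_D < 0
    face_valid: np.ndarray          # (F,) bool: survives the long-edge filter
    _tri: Delaunay | None = field(default=None, repr=False)

    @property
    def face_centres(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    def save_ply(self, path) -> None:
        import trimesh

        trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces[self.face_valid], process=False
        ).export(str(path))


def _grid_median(points: np.ndarray, cell_m: float) -> np.ndarray:
    """Median elevation of near-duplicate plan positions on a cell grid."""
    ij = np.round(points[:, :2] / cell_m).astype(np.int64)
    order = np.lexsort((ij[:, 1], ij[:, 0]))
    ij_s = ij[order]
    z_s = points[order, 2]
    uniq, starts = np.unique(ij_s, axis=0, return_index=True)
    out = np.empty((uniq.shape[0], 3))
    bounds = np.append(starts, ij_s.shape[0])
    for k in range(uniq.shape[0]):
        out[k, 2] = np.median(z_s[bounds[k]:bounds[k + 1]])
    out[:, :2] = uniq * cell_m
    return out


def _face_normals_ned(vertices: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    v0 = vertices[faces[:, 0]]
    e1 = vertices[faces[:, 1]] - v0
    e2 = vertices[faces[:, 2]] - v0
    n_enu = np.cross(e1, e2)
    norm = np.linalg.norm(n_enu, axis=1)
    degenerate = norm < 1e-12
    n_enu[degenerate] = [0.0, 0.0, 1.0]
    n_enu /= np.linalg.norm(n_enu, axis=1, keepdims=True)
    flip = n_enu[:, 2] < 0
    n_enu[flip] *= -1.0
    ned = np.column_stack([n_enu[:, 1], n_enu[:, 0], -n_enu[:, 2]])
    return ned, degenerate


def _elevation_outlier_filter(points: np.ndarray, coarse_m: float = 0.6,
                              max_dev_m: float | None = None) -> np.ndarray:
    """Reject points whose elevation departs from a robust local surface.

    A coarse per-cell median elevation grid is interpolated at each point;
    points further than ``max_dev_m`` (default: 6 x the global median
    absolute deviation from the coarse surface, floored at 0.25 m) are
    dropped.  Removes the isolated depth blunders dense matching produces.
    """
    from scipy import ndimage as ndi

    xy = points[:, :2]
    lo = xy.min(axis=0)
    ij = np.floor((xy - lo) / coarse_m).astype(np.int64)
    nx, ny = ij.max(axis=0) + 1
    flat = ij[:, 1] * nx + ij[:, 0]
    order = np.argsort(flat, kind="stable")
    cuts = np.concatenate([[0], np.flatnonzero(np.diff(flat[order])) + 1])
    med = np.full(nx * ny, np.nan)
    zs = points[order, 2]
    groups = np.split(zs, cuts[1:])
    med[flat[order][cuts]] = [np.median(g) for g in groups]
    grid = med.reshape(ny, nx)
    # fill empty cells from neighbours so edge points are not lost
    mask = np.isnan(grid)
    if mask.any():
        idx = ndi.distance_transform_edt(mask, return_distances=False,
                                         return_indices=True)
        grid = grid[tuple(idx)]
    local = ndi.map_coordinates(grid, [(xy[:, 1] - lo[1]) / coarse_m,
                                       (xy[:, 0] - lo[0]) / coarse_m],
                                order=1, mode="nearest")
    dev = np.abs(points[:, 2] - local)
    if max_dev_m is None:
        mad = np.median(dev)
        max_dev_m = max(6.0 * mad, 0.25)
    return dev <= max_dev_m


def triangulate_surface(
    points: np.ndarray,
    grid_cell_m: float | None = None,
    long_edge_factor: float = 10.0,
    outlier_filter: bool = True,
) -> TerrainMesh:
    """Delaunay-triangulate a pointcloud in plan view.

    ``grid_cell_m`` enables median-elevation gridding of near-duplicate plan
    positions (recommended for dense clouds); ``outlier_filter`` removes
    points far from a robust local median surface first; faces with an edge
    longer than ``long_edge_factor`` times the median edge length bridge
    data gaps and are flagged invalid.
    """
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 3:
        raise CollinearPointsError("need >= 3 points")
    if outlier_filter and points.shape[0] > 50:
        keep = _elevation_outlier_filter(points)
        if keep.sum() >= 3:
            points = points[keep]
    if grid_cell_m is not None:
        points = _grid_median(points, grid_cell_m)
    else:
        # collapse exact plan duplicates (keep first)
        _, idx = np.unique(np.round(points[:, :2], 9), axis=0, return_index=True)
        points = points[np.sort(idx)]
    if points.shape[0] < 3:
        raise CollinearPointsError("fewer than 3 distinct plan positions")
    try:
        tri = Delaunay(points[:, :2])
    except QhullError as e:
        raise CollinearPointsError(f"degenerate (collinear?) point set: {e}") from e
    if tri.simplices.shape[0] == 0:
        raise CollinearPointsError("triangulation produced no faces (collinear points)")
    faces = tri.simplices
    ned, degenerate = _face_normals_ned(points, faces)
    # long-edge filter in plan view
    p = points[:, :2]
    e = np.stack(
        [
            np.linalg.norm(p[faces[:, 0]] - p[faces[:, 1]], axis=1),
            np.linalg.norm(p[faces[:, 1]] - p[faces[:, 2]], axis=1),
            np.linalg.norm(p[faces[:, 2]] - p[faces[:, 0]], axis=1),
        ]
    )
    med = np.median(e)
    valid = (e.max(axis=0) <= long_edge_factor * med) & ~degenerate
    return TerrainMesh(vertices=points, faces=faces, normals_ned=ned,
                       face_valid=valid, _tri=tri)


def face_slope_aspect(mesh: TerrainMesh) -> tuple[np.ndarray, np.ndarray]:
    """Per-face slope and aspect in degrees.

    Horizontal faces (slope ~ 0) have undefined aspect, returned as NaN;
    degenerate faces are NaN in both.
    """
    n = mesh.normals_ned
    up = np.clip(-n[:, 2], -1.0, 1.0)
    slope = np.degrees(np.arccos(up))
    horiz = np.hypot(n[:, 0], n[:, 1])
    aspect = np.degrees(np.arctan2(n[:, 1], n[:, 0]))
    aspect = np.mod(aspect, 360.0)
    aspect[horiz < 1e-12] = np.nan
    bad = ~mesh.face_valid & np.isnan(slope)
    slope[bad] = np.nan
    return slope, aspect


def rasterize_terrain(
    mesh: TerrainMesh, cell_m: float, bounds: tuple[float, float, float, float] | None = None
) -> dict[str, RasterGrid]:
    """Elevation / slope / aspect rasters at ``cell_m`` resolution.

    Elevation is barycentric within the covering face; slope and aspect are
    the covering face's values.  Cells with no (valid) covering face are
    nodata.  Undefined aspect (horizontal faces) is nodata in the aspect
    band only.
    """
    if cell_m <= 0:
        raise ValueError("cell size must be positive")
    if mesh._tri is None or mesh.faces.shape[0] == 0:
        raise ValueError("empty mesh")
    if bounds is None:
        xmin, ymin = mesh.vertices[:, :2].min(axis=0)
        xmax, ymax = mesh.vertices[:, :2].max(axis=0)
    else:
        xmin, xmax, ymin, ymax = bounds
    x = np.arange(xmin + cell_m / 2.0, xmax, cell_m)
    y = np.arange(ymin + cell_m / 2.0, ymax, cell_m)
    XX, YY = np.meshgrid(x, y)
    pts = np.column_stack([XX.ravel(), YY.ravel()])
    simplex = mesh._tri.find_simplex(pts)
    inside = simplex >= 0
    valid = inside.copy()
    valid[inside] = mesh.face_valid[simplex[inside]]

    slope_f, aspect_f = face_slope_aspect(mesh)
    elev = np.full(pts.shape[0], NODATA)
    slope = np.full(pts.shape[0], NODATA)
    aspect = np.full(pts.shape[0], NODATA)

    if valid.any():
        s = simplex[valid]
        # barycentric coordinates
        T = mesh._tri.transform[s]
        r = pts[valid] - T[:, 2]
        bary2 = np.einsum("nij,nj->ni", T[:, :2], r)
        bary = np.column_stack([bary2, 1.0 - bary2.sum(axis=1)])
        zv = mesh.vertices[mesh.faces[s], 2]
        elev[valid] = np.einsum("ni,ni->n", bary, zv)
        slope[valid] = slope_f[s]
        a = aspect_f[s]
        aspect[valid] = np.where(np.isnan(a), NODATA, a)
        slope[valid] = np.where(np.isnan(slope_f[s]), NODATA, slope[valid])

    shape = XX.shape
    origin = (float(x[0]), float(y[0]))
    return {
        "elevation": RasterGrid(elev.reshape(shape), origin, cell_m, name="elevation"),
        "slope": RasterGrid(slope.reshape(shape), origin, cell_m, name="slope"),
        "aspect": RasterGrid(aspect.reshape(shape), origin, cell_m, name="aspect"),
    }
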