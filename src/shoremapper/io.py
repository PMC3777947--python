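"""File interchange: GeoTIFF rasters, 16-bit images, PLY clouds, CSV tables.

Rasters are written as GeoTIFFs (raw GeoTIFF tags on a plain TIFF container)
in the local ENU frame: the model-pixel-scale and model-tiepoint tags carry
the affine grid-to-world mapping and the ASCII citation records the geodetic
origin of the tangent plane.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .geodesy import GeodeticOrigin
from .terrain import NODATA, RasterGrid

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GEO_ASCII_PARAMS = 34737
_TAG_GDAL_NODATA = 42113


def write_geotiff(
    raster: RasterGrid, path, origin: GeodeticOrigin | None = None
) -> None:
    """Write a single-band float32 GeoTIFF.

    The raster's row 0 is the southernmost row; GeoTIFF rasters are stored
    north-up, so data are flipped and the tiepoint refers to the top-left
    (north-west) outer corner.
    """
    data = np.flipud(raster.data).astype(np.float32)
    ny = raster.data.shape[0]
    # outer corner of the NW cell (origin is a cell centre)
    west = raster.origin[0] - raster.cell_m / 2.0
    north = raster.origin[1] + (ny - 1) * raster.cell_m + raster.cell_m / 2.0
    citation = "Local ENU tangent plane"
    if origin is not None:
        citation += f" @ lat={origin.lat_deg:.6f} lon={origin.lon_deg:.6f}"
    citation += "|"
    # minimal key directory: user-defined projected CS, metre units
    keys = [
        1, 1, 0, 4,
        1024, 0, 1, 1,        # GTModelType = projected
        1025, 0, 1, 1,        # RasterPixelIsArea
        1026, _TAG_GEO_ASCII_PARAMS, len(citation), 0,  # citation
        3076, 0, 1, 9001,     # linear units = metre
    ]
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (raster.cell_m, raster.cell_m, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, west, north, 0.0)),
        (_TAG_GEO_KEY_DIRECTORY, "H", len(keys), tuple(keys)),
        (_TAG_GEO_ASCII_PARAMS, "s", len(citation), citation),
        (_TAG_GDAL_NODATA, "s", 0, str(raster.nodata)),
    ]
    tifffile.imwrite(str(path), data, extratags=extratags)


def read_geotiff(path) -> RasterGrid:
    """Read back a raster written by :func:`write_geotiff`."""
    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        data = page.asarray()
        scale = page.tags[_TAG_MODEL_PIXEL_SCALE].value
        tie = page.tags[_TAG_MODEL_TIEPOINT].value
        nodata = float(page.tags[_TAG_GDAL_NODATA].value)
    cell = float(scale[0])
    west, north = float(tie[3]), float(tie[4])
    ny = data.shape[0]
    data = np.flipud(data).astype(float)
    origin = (west + cell / 2.0, north - (ny - 1) * cell - cell / 2.0)
    return RasterGrid(data, origin, cell, nodata=nodata)


def write_image_16bit(pixels: np.ndarray, path, scale: float | None = None) -> float:
    """Write camera-linear float pixels as 16-bit TIFF; returns the scale used."""
    pixels = np.asarray(pixels)
    if scale is None:
        peak = float(pixels.max())
        scale = 60000.0 / peak if peak > 0 else 1.0
    out = np.clip(pixels * scale, 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), out, metadata={"linear_scale": scale})
    return scale


def read_image_16bit(path, scale: float) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.float32) / scale


def write_points_ply(points: np.ndarray, path) -> None:
    import trimesh

    trimesh.PointCloud(np.asarray(points, dtype=float)).export(str(path))


def read_points_ply(path) -> np.ndarray:
    import trimesh

    return np.asarray(trimesh.load(str(path)).vertices, dtype=float)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def read_json(path):
    return json.loads(Path(path).read_text())
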