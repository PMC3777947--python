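"""Multispectral pinhole rendering of synthetic scenes.

Each pixel's camera-linear value is the surface reflectance spectrum of the
hit point integrated against the channel's spectral sensitivity, scaled by
the camera's exposure time, and modulated by a per-class multiplicative
speckle texture (a stand-in for natural rock texture: local features need
gradients to latch onto).  The colour body yields 3-band images, the
near-infrared body 1-band images.  All geometry (poses, intrinsics, surface)
is recorded as ground truth for downstream oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ..geometry import CameraIntrinsics, CameraPose
from ..spectra import SpectralResponse, predict_band_response
from .flight import FlightPlan
from .scene import CLASS_NAMES, SceneModel

COLOUR_CHANNELS = ("red", "green", "blue")

#: Exposure times (s) of the two bodies; the NIR long-pass filter cuts light,
#: so the converted body needs a longer exposure.
DEFAULT_EXPOSURES = {"colour": 1.0 / 250.0, "nir": 1.0 / 100.0}


@dataclass
class ImageRecord:
    """One rendered frame: float32 camera-linear values."""

    image_id: str
    band: str                  # "colour" | "nir"
    pixels: np.ndarray         # (H, W, 3) for colour, (H, W) for nir

    @property
    def luminance(self) -> np.ndarray:
        if self.pixels.ndim == 2:
            return self.pixels
        return self.pixels.mean(axis=2)


@dataclass
class GroundTruth:
    """Everything the renderer knew: the oracle for downstream stages."""

    scene: SceneModel
    poses: dict[str, CameraPose]
    intrinsics: dict[str, CameraIntrinsics]      # per band
    class_band_values: dict[int, dict[str, float]]  # class idx -> channel -> integral
    exposures_s: dict[str, float]
    image_bands: dict[str, str]
    speckle: "SpeckleField | None" = None
    gcp_true_enu: np.ndarray | None = None
    waterline_enu: np.ndarray | None = None

    def surface_elevation(self, x, y) -> np.ndarray:
        return self.scene.elevation_at(x, y)

    def project(self, image_id: str, X: np.ndarray):
        from ..geometry import project_points

        band = self.image_bands[image_id]
        return project_points(X, self.poses[image_id], self.intrinsics[band])

    def band_value_at(self, x, y, band: str, channel: str) -> np.ndarray:
        """Noise-free rendered value at ground position(s) (x, y)."""
        cls = self.scene.class_at(x, y)
        base = np.array(
            [self.class_band_values[int(c)][channel] for c in np.atleast_1d(cls)]
        ) * self.exposures_s[band]
        if self.speckle is not None:
            base = base * self.speckle.sample(np.atleast_1d(cls), np.atleast_1d(x), np.atleast_1d(y))
        return base


class SpeckleField:
    """Per-class multiplicative speckle covering the scene (fixed seed).

    The field is non-repeating across the extent: periodic texture would let
    distant image pairs match each other consistently, which no natural rock
    surface does.
    """

    def __init__(
        self,
        n_classes: int,
        scale_m: float,
        amplitude: float,
        seed: int,
        extent: tuple[float, float, float, float],
        margin_m: float = 4.0,
    ):
        self.scale_m = scale_m
        self.amplitude = amplitude
        self.cell = scale_m / 2.5
        self.x0 = extent[0] - margin_m
        self.y0 = extent[2] - margin_m
        nx = int(np.ceil((extent[1] + margin_m - self.x0) / self.cell)) + 1
        ny = int(np.ceil((extent[3] + margin_m - self.y0) / self.cell)) + 1
        sigma = 1.25  # cells -> correlation length ~ scale_m
        self.fields = []
        for c in range(n_classes):
            rng = np.random.default_rng((seed, 7919 + c))
            g = ndimage.gaussian_filter(rng.standard_normal((ny, nx)), sigma)
            g /= g.std()
            self.fields.append(
                np.maximum(1.0 + amplitude * g, 0.05).astype(np.float32)
            )

    def sample(self, cls: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        if self.amplitude == 0.0:
            return np.ones_like(np.asarray(x, dtype=float))
        r = (np.asarray(y, dtype=float) - self.y0) / self.cell
        c = (np.asarray(x, dtype=float) - self.x0) / self.cell
        out = np.empty(np.broadcast(r, c).shape, dtype=float)
        cls = np.asarray(cls)
        for k in np.unique(cls):
            m = cls == k
            out[m] = ndimage.map_coordinates(
                self.fields[int(k) % len(self.fields)],
                [np.atleast_1d(r)[m], np.atleast_1d(c)[m]],
                order=1, mode="nearest",
            )
        return out


class PoseBelowTerrainError(ValueError):
    pass


def _class_band_values(
    scene: SceneModel, responses: dict[str, SpectralResponse]
) -> dict[int, dict[str, float]]:
    out: dict[int, dict[str, float]] = {}
    for name, spec in scene.class_spectra.items():
        idx = CLASS_NAMES.index(name)
        out[idx] = {ch: predict_band_response(spec, r).value for ch, r in responses.items()}
    return out


def render_views(
    scene: SceneModel,
    plan: FlightPlan,
    responses: dict[str, SpectralResponse],
    noise_sd: float = 0.0,
    seed: int = 0,
    texture_scale_m: float = 0.08,
    texture_amplitude: float = 0.35,
    exposures_s: dict[str, float] | None = None,
    ray_iters: int = 30,
    ground_truth: GroundTruth | None = None,
) -> tuple[list[ImageRecord], GroundTruth]:
    """Render every pose of a flight plan.

    ``noise_sd`` is additive Gaussian noise as a fraction of the mean image
    value.  Passing an existing ``ground_truth`` accumulates a second band's
    flight into the same truth record (shared scene and speckle).
    """
    if plan.band == "colour":
        channels = COLOUR_CHANNELS
    elif plan.band == "nir":
        channels = ("nir",)
    else:
        raise ValueError(f"unknown band {plan.band!r}")
    for ch in channels:
        if ch not in responses:
            raise ValueError(f"missing spectral response for channel {ch!r}")
    grids = [responses[ch].wavelength_nm for ch in channels]
    for g in grids[1:]:
        if g.shape != grids[0].shape or not np.allclose(g, grids[0]):
            raise ValueError("responses must share a common wavelength grid")

    exposures = dict(DEFAULT_EXPOSURES if exposures_s is None else exposures_s)
    t_exp = exposures[plan.band]
    intr = plan.intrinsics
    band_values = _class_band_values(scene, responses)

    if ground_truth is None:
        speckle = (
            SpeckleField(len(CLASS_NAMES), texture_scale_m, texture_amplitude,
                         scene.seed, scene.extent)
            if texture_amplitude > 0
            else None
        )
        gt = GroundTruth(
            scene=scene, poses={}, intrinsics={}, class_band_values=band_values,
            exposures_s=exposures, image_bands={}, speckle=speckle,
        )
    else:
        gt = ground_truth
        gt.class_band_values.update(band_values)
        gt.exposures_s.update(exposures)
        speckle = gt.speckle
    gt.intrinsics[plan.band] = intr

    rng = np.random.default_rng((seed, 104729))
    H, W = intr.height, intr.width
    u, v = np.meshgrid(np.arange(W, dtype=float), np.arange(H, dtype=float))
    xn, yn = intr.pixel_to_normalized(u.ravel(), v.ravel())
    dirs_cam = np.column_stack([xn, yn, np.ones_like(xn)])

    images: list[ImageRecord] = []
    z_mean = float(np.mean(scene.heightfield))
    prefix = "col" if plan.band == "colour" else "nir"
    for i, pose in enumerate(plan.poses):
        gz = float(scene.elevation_at(pose.C[0], pose.C[1]))
        if pose.C[2] <= gz:
            raise PoseBelowTerrainError(
                f"pose {i} at z={pose.C[2]:.2f} is below the terrain ({gz:.2f})"
            )
        d = dirs_cam @ pose.R  # world-frame ray directions, rows
        dz = d[:, 2]
        if np.any(dz >= -1e-6):
            raise PoseBelowTerrainError(f"pose {i} has rays not looking down")
        # fixed-point ray/heightfield intersection
        z = np.full(d.shape[0], z_mean)
        for _ in range(ray_iters):
            t = (z - pose.C[2]) / dz
            px = pose.C[0] + t * d[:, 0]
            py = pose.C[1] + t * d[:, 1]
            z = scene.elevation_at(px, py)
        cls = scene.class_at(px, py)
        tex = speckle.sample(cls, px, py) if speckle is not None else 1.0

        bands = []
        for ch in channels:
            base = np.array([band_values.get(k, {}).get(ch, 0.0)
                             for k in range(len(CLASS_NAMES))])
            vals = base[cls] * t_exp * tex
            bands.append(vals.reshape(H, W))
        img = np.stack(bands, axis=2) if len(bands) > 1 else bands[0]
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd * img.mean(), size=img.shape)
            img = np.maximum(img, 0.0)
        image_id = f"{prefix}_{i:03d}"
        images.append(ImageRecord(image_id=image_id, band=plan.band,
                                  pixels=img.astype(np.float32)))
        gt.poses[image_id] = pose
        gt.image_bands[image_id] = plan.band
    return images, gt


def spectralon_values(
    responses: dict[str, SpectralResponse],
    exposures_s: dict[str, float] | None = None,
    reflectance: float = 0.99,
) -> dict[str, float]:
    """Camera-linear channel means a Spectralon white target would produce."""
    exposures = DEFAULT_EXPOSURES if exposures_s is None else exposures_s
    out = {}
    for ch, resp in responses.items():
        band = "nir" if ch == "nir" else "colour"
        out[ch] = reflectance * resp.integral() * exposures[band]
    return out
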