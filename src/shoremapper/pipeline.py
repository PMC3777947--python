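"""End-to-end pipeline orchestration with stage caching and a synthetic demo.

Stages (in order): match -> sfm -> densify -> georef -> terrain -> mosaic ->
ndvi.  Each stage records a hash of its parameters and its inputs' hashes in
the run manifest; a rerun with identical inputs and parameters skips the
stage, and any change invalidates the stage and everything downstream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pickle
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as smio
from .epipolar import filter_epipolar
from .features import extract_features, match_pair
from .geodesy import DEFAULT_ORIGIN, GeodeticOrigin
from .geometry import CameraIntrinsics
from .georef import (
    adjust_vertical_datum,
    attach_annotations,
    georegister,
    read_annotations_csv,
    read_gcps_csv,
)
from .sfm import densify, run_incremental_sfm
from .terrain import rasterize_terrain, triangulate_surface
from .tracks import build_tracks, match_statistics
from . import texturing as tx

log = logging.getLogger(__name__)

STAGES = ["match", "sfm", "densify", "georef", "terrain", "mosaic", "ndvi"]


@dataclass
class PipelineConfig:
    """All paths and stage parameters of one run; seed is mandatory."""

    colour_dir: str
    nir_dir: str | None
    gcps_csv: str
    annotations_csv: str
    waterline_csv: str
    out_dir: str
    seed: int
    origin: GeodeticOrigin = field(default_factory=lambda: DEFAULT_ORIGIN)
    datum_height_m: float = 0.16
    image_scale_json: str | None = None

    # feature/matching
    sift_c_dog: float = 0.004
    match_ratio: float = 0.8
    epi_threshold_px: float = 2.0
    pair_prefilter: bool = False

    # sfm
    focal_prior_colour: float = 430.0
    focal_prior_nir: float = 445.0
    pnp_px: float = 4.0
    min_tri_angle_deg: float = 2.0
    huber_px: float = 2.0
    min_init_inliers: int = 100

    # densify
    densify_cell_px: int = 5
    zncc_min: float = 0.7

    # terrain / mosaic
    terrain_grid_m: float = 0.12
    raster_cell_m: float = 0.08
    mosaic_cell_m: float = 0.08

    # ndvi
    spectralon_red: float = 1.0
    spectralon_nir: float = 1.0
    exposure_colour_s: float = 1.0
    exposure_nir_s: float = 1.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["origin"] = self.origin.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if isinstance(d.get("origin"), dict):
            d["origin"] = GeodeticOrigin.from_dict(d["origin"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def save_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


@dataclass
class RunManifest:
    stages: dict = field(default_factory=dict)
    config_echo: dict = field(default_factory=dict)

    def save(self, path) -> None:
        smio.write_json({"stages": self.stages, "config": self.config_echo}, path)

    @classmethod
    def load(cls, path) -> "RunManifest":
        d = smio.read_json(path)
        return cls(stages=d["stages"], config_echo=d.get("config", {}))

    def fingerprint(self) -> str:
        """Content hash over stage results: parameters and output hashes,
        with wall-clock times and absolute paths stripped.  Two runs of the
        same survey with the same seed produce identical fingerprints."""
        canon = {}
        for name, entry in sorted(self.stages.items()):
            canon[name] = {
                "status": entry.get("status"),
                "params": entry.get("params"),
                "output_hashes": {
                    Path(p).name: h
                    for p, h in sorted(entry.get("output_hashes", {}).items())
                },
            }
        return _hash_obj(canon)


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()[:16]


class PipelineRunner:
    """Executes the stage graph with hash-based caching."""

    def __init__(self, config: PipelineConfig):
        self.cfg = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        if self.manifest_path.exists():
            self.manifest = RunManifest.load(self.manifest_path)
        else:
            self.manifest = RunManifest()
        self.manifest.config_echo = config.to_dict()
        self._mem: dict = {}

    # -- caching infrastructure -------------------------------------------
    def _stage_hash(self, name: str, params: dict, upstream: list[str],
                    input_files: list[Path]) -> str:
        parts = {
            "params": params,
            "upstream": [self.manifest.stages.get(u, {}).get("hash") for u in upstream],
            "files": {str(p): _hash_file(p) for p in sorted(input_files)},
        }
        return _hash_obj(parts)

    def _cached(self, name: str, h: str, outputs: list[Path]) -> bool:
        entry = self.manifest.stages.get(name)
        if not entry or entry.get("hash") != h or entry.get("status") != "done":
            return False
        if any(not Path(p).exists() for p in entry.get("outputs", [])):
            return False
        # artefact integrity: stored output hashes must still match
        for p, fh in entry.get("output_hashes", {}).items():
            if not Path(p).exists() or _hash_file(Path(p)) != fh:
                return False
        return True

    def _record(self, name: str, h: str, outputs: list[Path], t0: float,
                extra: dict | None = None) -> None:
        self.manifest.stages[name] = {
            "status": "done",
            "hash": h,
            "outputs": [str(p) for p in outputs],
            "output_hashes": {str(p): _hash_file(Path(p)) for p in outputs},
            "wall_s": round(time.time() - t0, 2),
            "params": (extra or {}),
        }
        self.manifest.save(self.manifest_path)

    def _fail(self, name: str, err: Exception) -> None:
        self.manifest.stages[name] = {"status": "failed", "error": str(err)}
        self.manifest.save(self.manifest_path)

    # -- image loading -----------------------------------------------------
    def _load_images(self) -> tuple[dict, dict]:
        scales = {}
        if self.cfg.image_scale_json and Path(self.cfg.image_scale_json).exists():
            scales = smio.read_json(self.cfg.image_scale_json)
        images: dict[str, np.ndarray] = {}
        bands: dict[str, str] = {}
        for band, d in (("colour", self.cfg.colour_dir), ("nir", self.cfg.nir_dir)):
            if d is None:
                continue
            for p in sorted(Path(d).glob("*.tif*")):
                iid = p.stem
                s = float(scales.get(iid, 1.0))
                images[iid] = smio.read_image_16bit(p, s)
                bands[iid] = band
        if not images:
            raise FileNotFoundError(f"no images found under {self.cfg.colour_dir}")
        return images, bands

    def _image_files(self) -> list[Path]:
        files = []
        for d in (self.cfg.colour_dir, self.cfg.nir_dir):
            if d is not None:
                files.extend(sorted(Path(d).glob("*.tif*")))
        return files

    # -- stages ------------------------------------------------------------
    def stage_match(self) -> None:
        cfg = self.cfg
        params = {"c_dog": cfg.sift_c_dog, "ratio": cfg.match_ratio,
                  "epi": cfg.epi_threshold_px, "seed": cfg.seed}
        h = self._stage_hash("match", params, [], self._image_files())
        out_pkl = self.out / "tracks.pkl"
        out_csv = self.out / "matches.csv"
        if self._cached("match", h, [out_pkl, out_csv]):
            log.info("match: cached")
            return
        t0 = time.time()
        images, bands = self._load_images()
        fsets = {i: extract_features(images[i], i, c_dog=cfg.sift_c_dog)
                 for i in sorted(images)}
        ids = sorted(fsets)
        pms = []
        rows = []
        for a_i in range(len(ids)):
            for b_i in range(a_i + 1, len(ids)):
                a, b = ids[a_i], ids[b_i]
                cand = match_pair(fsets[a], fsets[b], ratio=cfg.match_ratio)
                pm = filter_epipolar(
                    fsets[a].keypoints, fsets[b].keypoints, cand,
                    threshold_px=cfg.epi_threshold_px,
                    seed=(cfg.seed * 100003 + a_i * 131 + b_i) % 2**31,
                    image_a=a, image_b=b,
                )
                pms.append(pm)
                rows.append({"img_a": a, "img_b": b, "n_candidates": len(cand),
                             "n_inliers": pm.n_inliers})
        tg = build_tracks(pms, bands)
        kps = {i: fsets[i].keypoints for i in ids}
        with open(out_pkl, "wb") as fh:
            pickle.dump({"tracks": tg, "keypoints": kps, "bands": bands}, fh)
        pd.DataFrame(rows).to_csv(out_csv, index=False)
        stats = match_statistics(pms, bands)
        log.info("match statistics:\n%s", stats.to_string(index=False))
        self._record("match", h, [out_pkl, out_csv], t0, params)

    def stage_sfm(self) -> None:
        cfg = self.cfg
        params = {"pnp": cfg.pnp_px, "angle": cfg.min_tri_angle_deg,
                  "huber": cfg.huber_px, "seed": cfg.seed,
                  "f0": [cfg.focal_prior_colour, cfg.focal_prior_nir]}
        h = self._stage_hash("sfm", params, ["match"], [])
        out_pkl = self.out / "model.pkl"
        out_json = self.out / "model.json"
        out_ply = self.out / "sparse.ply"
        if self._cached("sfm", h, [out_pkl, out_json, out_ply]):
            log.info("sfm: cached")
            return
        t0 = time.time()
        with open(self.out / "tracks.pkl", "rb") as fh:
            d = pickle.load(fh)
        images, bands = self._load_images()
        some = next(iter(images.values()))
        height, width = some.shape[:2]
        priors = {
            "colour": CameraIntrinsics(cfg.focal_prior_colour, (width - 1) / 2.0,
                                       (height - 1) / 2.0, width=width, height=height),
            "nir": CameraIntrinsics(cfg.focal_prior_nir, (width - 1) / 2.0,
                                    (height - 1) / 2.0, width=width, height=height),
        }
        model = run_incremental_sfm(
            d["tracks"], d["keypoints"], d["bands"], priors, seed=cfg.seed,
            pnp_px=cfg.pnp_px, min_tri_angle_deg=cfg.min_tri_angle_deg,
            huber_px=cfg.huber_px, min_init_inliers=cfg.min_init_inliers,
        )
        with open(out_pkl, "wb") as fh:
            pickle.dump(model, fh)
        model.save_json(out_json)
        model.save_ply(out_ply)
        self._record("sfm", h, [out_pkl, out_json, out_ply], t0, params)

    def stage_densify(self) -> None:
        cfg = self.cfg
        params = {"cell_px": cfg.densify_cell_px, "zncc": cfg.zncc_min}
        h = self._stage_hash("densify", params, ["sfm"], [])
        out_pkl = self.out / "dense.pkl"
        out_ply = self.out / "dense.ply"
        if self._cached("densify", h, [out_pkl, out_ply]):
            log.info("densify: cached")
            return
        t0 = time.time()
        model = self._load_model()
        images, _ = self._load_images()
        stats = densify(model, images, cell_px=cfg.densify_cell_px,
                        zncc_min=cfg.zncc_min)
        with open(out_pkl, "wb") as fh:
            pickle.dump(model, fh)
        model.save_ply(out_ply, dense=True)
        log.info("densify: %d points, density/cell %.3f",
                 stats["n_dense"], stats["density_per_cell"])
        self._record("densify", h, [out_pkl, out_ply], t0,
                     {**params, "n_dense": stats["n_dense"],
                      "density_per_cell": stats["density_per_cell"]})

    def _load_model(self, stage: str = "densify"):
        for name in {"densify": ["dense.pkl", "model.pkl"],
                     "georef": ["georef.pkl", "dense.pkl", "model.pkl"]}.get(
                         stage, ["model.pkl"]):
            p = self.out / name
            if p.exists():
                with open(p, "rb") as fh:
                    return pickle.load(fh)
        raise FileNotFoundError("no model artefact found; run sfm first")

    def stage_georef(self) -> None:
        cfg = self.cfg
        params = {"datum": cfg.datum_height_m, "origin": cfg.origin.to_dict()}
        inputs = [Path(cfg.gcps_csv), Path(cfg.annotations_csv)]
        if Path(cfg.waterline_csv).exists():
            inputs.append(Path(cfg.waterline_csv))
        h = self._stage_hash("georef", params, ["densify"], inputs)
        out_pkl = self.out / "georef.pkl"
        out_json = self.out / "residuals.json"
        if self._cached("georef", h, [out_pkl, out_json]):
            log.info("georef: cached")
            return
        t0 = time.time()
        model = self._load_model("densify")
        gcps = read_gcps_csv(cfg.gcps_csv)
        attach_annotations(gcps, read_annotations_csv(cfg.annotations_csv))
        tf, report = georegister(gcps, cfg.origin)
        if Path(cfg.waterline_csv).exists():
            wl = pd.read_csv(cfg.waterline_csv)[["x", "y", "z"]].to_numpy()
            tf, shift = adjust_vertical_datum(tf, tf.apply(wl), cfg.datum_height_m)
        else:
            shift = 0.0
        model.apply_similarity(tf)
        with open(out_pkl, "wb") as fh:
            pickle.dump({"model": model, "transform": tf, "report": report}, fh)
        smio.write_json({**report.to_dict(), "vertical_shift_m": shift}, out_json)
        log.info("georef: global %.3f m, local %.4f m",
                 report.global_residual_m, report.local_residual_m)
        self._record("georef", h, [out_pkl, out_json], t0, params)

    def stage_terrain(self) -> None:
        cfg = self.cfg
        params = {"grid": cfg.terrain_grid_m, "cell": cfg.raster_cell_m}
        h = self._stage_hash("terrain", params, ["georef"], [])
        outs = [self.out / "terrain.ply", self.out / "terrain.pkl"] + [
            self.out / f"{b}.tif" for b in ("elevation", "slope", "aspect")
        ]
        if self._cached("terrain", h, outs):
            log.info("terrain: cached")
            return
        t0 = time.time()
        with open(self.out / "georef.pkl", "rb") as fh:
            model = pickle.load(fh)["model"]
        mesh = triangulate_surface(model.dense_points, grid_cell_m=cfg.terrain_grid_m)
        rasters = rasterize_terrain(mesh, cfg.raster_cell_m)
        mesh.save_ply(self.out / "terrain.ply")
        with open(self.out / "terrain.pkl", "wb") as fh:
            pickle.dump(mesh, fh)
        for name, r in rasters.items():
            smio.write_geotiff(r, self.out / f"{name}.tif", origin=cfg.origin)
        self._record("terrain", h, outs, t0, params)

    def stage_mosaic(self) -> None:
        cfg = self.cfg
        params = {"cell": cfg.mosaic_cell_m}
        h = self._stage_hash("mosaic", params, ["terrain"], [])
        band_names = ["R", "G", "B", "NIR"]
        outs = [self.out / f"mosaic_{b}.tif" for b in band_names]
        if self._cached("mosaic", h, outs):
            log.info("mosaic: cached")
            return
        t0 = time.time()
        with open(self.out / "georef.pkl", "rb") as fh:
            model = pickle.load(fh)["model"]
        with open(self.out / "terrain.pkl", "rb") as fh:
            mesh = pickle.load(fh)
        images, _ = self._load_images()
        assignment = tx.select_views(mesh, model)
        mosaic = tx.render_orthomosaic(mesh, assignment, images, model,
                                       cfg.mosaic_cell_m)
        for b in band_names:
            if b in mosaic.bands:
                smio.write_geotiff(mosaic.bands[b], self.out / f"mosaic_{b}.tif",
                                   origin=cfg.origin)
        self._record("mosaic", h, [p for p in outs if p.exists()], t0, params)

    def stage_ndvi(self) -> None:
        cfg = self.cfg
        params = {"spectralon": [cfg.spectralon_red, cfg.spectralon_nir],
                  "exposures": [cfg.exposure_colour_s, cfg.exposure_nir_s]}
        h = self._stage_hash("ndvi", params, ["mosaic"], [])
        out_tif = self.out / "ndvi.tif"
        if self._cached("ndvi", h, [out_tif]):
            log.info("ndvi: cached")
            return
        t0 = time.time()
        R = smio.read_geotiff(self.out / "mosaic_R.tif")
        N = smio.read_geotiff(self.out / "mosaic_NIR.tif")
        mosaic = tx.OrthoMosaic(bands={"R": R, "NIR": N})
        gains = tx.white_balance_gains(
            {"red": cfg.spectralon_red, "nir": cfg.spectralon_nir},
            {"colour": cfg.exposure_colour_s, "nir": cfg.exposure_nir_s},
        )
        ndvi = tx.compute_ndvi(mosaic, gains,
                               (cfg.exposure_colour_s, cfg.exposure_nir_s))
        smio.write_geotiff(ndvi.grid, out_tif, origin=cfg.origin)
        self._record("ndvi", h, [out_tif], t0,
                     {**params, "gains": list(gains)})

    def run(self, stages: list[str] | None = None) -> RunManifest:
        for name in stages or STAGES:
            fn = getattr(self, f"stage_{name}")
            try:
                fn()
            except Exception as e:  # noqa: BLE001 - recorded and re-raised
                self._fail(name, e)
                raise
        return self.manifest


def run_pipeline(config: PipelineConfig, stages: list[str] | None = None) -> RunManifest:
    return PipelineRunner(config).run(stages)
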