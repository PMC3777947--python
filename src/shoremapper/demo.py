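"""One-command synthetic survey: generate, fly, render, run, validate.

``make_survey`` writes a complete synthetic survey to disk (images, GCP
table, annotations, waterline, config) exactly as a field survey would
provide them; ``demo_synthetic`` runs the full pipeline on it and compares
every product against the recorded ground truth, returning an accuracy
report with pass/fail flags for the documented accuracy properties.
"""

from __future__ import annotations

import logging
import pickle
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as smio
from .georef import horn_align
from .pipeline import PipelineConfig, RunManifest, run_pipeline
from .spectra import default_camera_responses, predict_ndvi
from .synthetic import (
    extract_waterline,
    generate_scene,
    place_gcps,
    plan_flight,
    render_views,
)
from .synthetic.annotate import annotate_gcps, waterline_in_reconstruction
from .synthetic.render import DEFAULT_EXPOSURES, spectralon_values
from .synthetic.scene import CLASS_NAMES, gcps_to_csv

log = logging.getLogger(__name__)


@dataclass
class SurveyTruth:
    """Everything needed to score pipeline products against ground truth."""

    scene: object
    ground_truth: object
    gcp_true_enu: np.ndarray
    config: PipelineConfig
    image_dirs: dict[str, Path]


def make_survey(
    out_dir,
    seed: int = 42,
    scale: float = 1.0,
    n_colour: int = 24,
    n_nir: int = 20,
    size_m: tuple[float, float] = (68.0, 28.0),
    gps_noise_sd_m: float = 0.0,
    noise_sd: float = 0.0,
    altitude_m: float = 15.0,
    write_images: bool = True,
) -> SurveyTruth:
    """Generate and (optionally) write a synthetic survey.

    ``scale`` scales the image dimensions linearly (1.0 -> 640x480); the
    flight and scene are unchanged, so ground sampling distance scales as
    1/scale.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng((seed, 11))
    scene = generate_scene(size_m=size_m, seed=seed)
    resp = default_camera_responses()

    from .geometry import CameraIntrinsics

    width, height = int(round(640 * scale)), int(round(480 * scale))
    intr_c = CameraIntrinsics(450.0 * scale, (width - 1) / 2.0, (height - 1) / 2.0,
                              k1=-0.06, k2=0.012, width=width, height=height)
    intr_n = CameraIntrinsics(462.0 * scale, (width - 1) / 2.0, (height - 1) / 2.0,
                              k1=-0.05, k2=0.010, width=width, height=height)

    plan_c = plan_flight(scene, altitude_m=altitude_m, overlap=0.55,
                         seed=int(rng.integers(2**31)), n_images=n_colour,
                         intrinsics=intr_c, jitter_rot_deg=3.5, jitter_trans_m=0.5)
    texture_scale = 0.08 / scale   # keep texture resolvable at ~2.5 x GSD
    imgs_c, gt = render_views(scene, plan_c, resp, noise_sd=noise_sd,
                              texture_scale_m=texture_scale,
                              seed=int(rng.integers(2**31)))
    plan_n = plan_flight(scene, altitude_m=altitude_m + 1.5, overlap=0.55,
                         seed=int(rng.integers(2**31)), band="nir", n_images=n_nir,
                         intrinsics=intr_n, start_offset_m=2.5,
                         jitter_rot_deg=3.5, jitter_trans_m=0.5)
    imgs_n, gt = render_views(scene, plan_n, resp, noise_sd=noise_sd,
                              texture_scale_m=texture_scale,
                              seed=int(rng.integers(2**31)), ground_truth=gt)

    gcps, true_enu = place_gcps(scene, n_triads=3, edge_m=2.0,
                                gps_noise_sd_m=gps_noise_sd_m,
                                seed=int(rng.integers(2**31)))
    gt.gcp_true_enu = true_enu
    waterline = extract_waterline(scene)
    gt.waterline_enu = waterline

    col_dir = out / "colour"
    nir_dir = out / "nir"
    scales = {}
    if write_images:
        col_dir.mkdir(exist_ok=True)
        nir_dir.mkdir(exist_ok=True)
        peak = max(max(float(im.pixels.max()) for im in imgs_c),
                   max(float(im.pixels.max()) for im in imgs_n))
        common = 60000.0 / peak if peak > 0 else 1.0
        for im in imgs_c:
            smio.write_image_16bit(im.pixels, col_dir / f"{im.image_id}.tif", common)
            scales[im.image_id] = common
        for im in imgs_n:
            smio.write_image_16bit(im.pixels, nir_dir / f"{im.image_id}.tif", common)
            scales[im.image_id] = common
        smio.write_json(scales, out / "image_scales.json")
    gcps_to_csv(gcps, out / "gcps.csv")
    pd.DataFrame(waterline, columns=["x", "y", "z"]).to_csv(
        out / "waterline_enu.csv", index=False
    )

    sv = spectralon_values(resp)
    config = PipelineConfig(
        colour_dir=str(col_dir), nir_dir=str(nir_dir),
        gcps_csv=str(out / "gcps.csv"),
        annotations_csv=str(out / "annotations.csv"),
        waterline_csv=str(out / "waterline_recon.csv"),
        out_dir=str(out / "products"),
        seed=seed, origin=scene.origin, datum_height_m=scene.water_datum,
        image_scale_json=str(out / "image_scales.json"),
        focal_prior_colour=430.0 * scale, focal_prior_nir=445.0 * scale,
        terrain_grid_m=0.12 / scale, raster_cell_m=0.08 / scale,
        mosaic_cell_m=0.08 / scale,
        min_init_inliers=int(max(30, round(100 * scale * scale))),
        spectralon_red=sv["red"], spectralon_nir=sv["nir"],
        exposure_colour_s=DEFAULT_EXPOSURES["colour"],
        exposure_nir_s=DEFAULT_EXPOSURES["nir"],
    )
    config.save_yaml(out / "config.yaml")
    with open(out / "truth.pkl", "wb") as fh:
        pickle.dump({"gt": gt, "scene": scene, "gcps": gcps, "true_enu": true_enu}, fh)
    return SurveyTruth(scene=scene, ground_truth=gt, gcp_true_enu=true_enu,
                       config=config, image_dirs={"colour": col_dir, "nir": nir_dir})


def demo_synthetic(
    out_dir,
    seed: int = 42,
    scale: float = 1.0,
    gps_noise_sd_m: float = 0.0,
    **survey_kwargs,
) -> tuple[RunManifest, dict]:
    """Run the whole pipeline on a synthetic survey; score against truth.

    Returns (manifest, report).  ``report["passed"]`` aggregates the
    documented accuracy properties; any failure makes it False.
    """
    t0 = time.time()
    out = Path(out_dir)
    survey = make_survey(out, seed=seed, scale=scale,
                         gps_noise_sd_m=gps_noise_sd_m, **survey_kwargs)
    cfg = survey.config
    scene = survey.scene
    gt = survey.ground_truth

    # match + sfm first: GCP/waterline annotations come from the model frame
    manifest = run_pipeline(cfg, stages=["match", "sfm"])
    with open(Path(cfg.out_dir) / "model.pkl", "rb") as fh:
        model = pickle.load(fh)
    with open(out / "truth.pkl", "rb") as fh:
        truth = pickle.load(fh)
    gcps = truth["gcps"]
    annotate_gcps(model, gt, gcps, survey.gcp_true_enu)
    pd.DataFrame(
        [{"gcp_id": g.gcp_id, "x": g.recon_xyz[0], "y": g.recon_xyz[1],
          "z": g.recon_xyz[2]} for g in gcps]
    ).to_csv(cfg.annotations_csv, index=False)
    wl_rec = waterline_in_reconstruction(model, gt, gt.waterline_enu)
    pd.DataFrame(wl_rec, columns=["x", "y", "z"]).to_csv(cfg.waterline_csv, index=False)

    manifest = run_pipeline(cfg)

    report = score_against_truth(cfg, survey, scale=scale)
    report["wall_s"] = round(time.time() - t0, 1)
    smio.write_json(report, out / "accuracy_report.json")
    return manifest, report


def score_against_truth(cfg: PipelineConfig, survey: SurveyTruth, scale: float = 1.0) -> dict:
    """Compare every pipeline product with the survey's ground truth."""
    out = Path(cfg.out_dir)
    scene = survey.scene
    gt = survey.ground_truth
    with open(out / "georef.pkl", "rb") as fh:
        geo = pickle.load(fh)
    model = geo["model"]
    report_res = geo["report"]

    n_images = len(gt.poses)
    frac_registered = model.n_registered / n_images

    reg = [i for i in model.registration_order if i in gt.poses]
    C_rec = np.array([model.poses[i].C for i in reg])
    C_true = np.array([gt.poses[i].C for i in reg])
    tf, res = horn_align(C_rec, C_true, estimate_scale_flag=True)
    cam_rmse = float(np.sqrt((res**2).mean()))
    altitude = float(np.mean(C_true[:, 2] - scene.elevation_at(C_true[:, 0], C_true[:, 1])))
    gsd = altitude * 1.0 / model.intrinsics["colour"].focal   # metres per pixel
    topo_gsd = cfg.densify_cell_px * gsd   # dense-cloud sampling distance

    dense = model.dense_points
    dz = dense[:, 2] - scene.elevation_at(dense[:, 0], dense[:, 1])
    dense_median = float(np.median(np.abs(dz)))

    elev = smio.read_geotiff(out / "elevation.tif")
    m = elev.defined_mask()
    XX, YY = elev.cell_centres()
    err = elev.data[m] - scene.elevation_at(XX[m], YY[m])
    elev_rmse = float(np.sqrt((err**2).mean()))

    # densification density (from the manifest's densify stage record)
    manifest = RunManifest.load(out / "manifest.json")
    density = manifest.stages["densify"]["params"].get("density_per_cell", np.nan)

    # per-class NDVI against closed-form prediction
    ndvi = smio.read_geotiff(out / "ndvi.tif")
    gains = tuple(manifest.stages["ndvi"]["params"]["gains"])
    resp = default_camera_responses()
    mm = ndvi.defined_mask()
    XXn, YYn = ndvi.cell_centres()
    cls = scene.class_at(XXn[mm], YYn[mm])
    exposures = (cfg.exposure_colour_s, cfg.exposure_nir_s)
    ndvi_rows = {}
    worst_diff = 0.0
    for name, spec in scene.class_spectra.items():
        k = CLASS_NAMES.index(name)
        sel = cls == k
        if sel.sum() < 100:
            continue
        measured = float(np.median(ndvi.data[mm][sel]))
        predicted = float(predict_ndvi(spec, resp["red"], resp["nir"], gains,
                                       exposures_s=exposures))
        ndvi_rows[name] = {"measured": measured, "predicted": predicted,
                           "difference": measured - predicted}
        worst_diff = max(worst_diff, abs(measured - predicted))

    checks = {
        "registration_rate_ge_90pct": frac_registered >= 0.9,
        "camera_rmse_lt_1pct_altitude": cam_rmse < 0.01 * altitude,
        "dense_median_error_lt_2x_topo_gsd": dense_median < 2.0 * topo_gsd,
        "elevation_rmse_lt_2x_topo_gsd": elev_rmse < 2.0 * topo_gsd,
        "density_within_2x": 0.5 <= density <= 2.0,
        "ndvi_class_agreement_lt_0p05": worst_diff < 0.05 if ndvi_rows else False,
        "local_residual_small": report_res.local_residual_m < 1e-3,
    }
    report = {
        "n_images": n_images,
        "n_registered": model.n_registered,
        "frac_registered": frac_registered,
        "reprojection_rmse_px": model.reprojection_rmse,
        "camera_centre_rmse_m": cam_rmse,
        "altitude_m": altitude,
        "gsd_m": gsd,
        "topographic_gsd_m": topo_gsd,
        "dense_median_abs_error_m": dense_median,
        "elevation_raster_rmse_m": elev_rmse,
        "density_per_cell": density,
        "global_residual_m": report_res.global_residual_m,
        "local_residual_m": report_res.local_residual_m,
        "ndvi_by_class": ndvi_rows,
        "checks": checks,
        "passed": all(checks.values()),
    }
    return report
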