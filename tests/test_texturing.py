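import numpy as np
import pandas as pd
import pytest

from shoremapper import texturing as tx
from shoremapper.geometry import CameraIntrinsics, CameraPose
from shoremapper.sfm.model import ReconstructionModel
from shoremapper.terrain import NODATA, RasterGrid, triangulate_surface
from shoremapper.tracks import TrackGraph


def truth_model(poses, intrinsics, bands):
    """Reconstruction container holding known poses (no SfM involved)."""
    order = sorted(poses)
    return ReconstructionModel(
        track_graph=TrackGraph(tracks=[]), keypoints={},
        image_bands=dict(bands), intrinsics=dict(intrinsics),
        poses=dict(poses), registration_order=order,
    )


def make_flat_setup():
    """Flat textureless plane seen by 6 nadir colour cameras + 2 NIR."""
    intr = CameraIntrinsics(200.0, 79.5, 59.5, width=160, height=120)
    nadir = np.array([[1.0, 0, 0], [0, -1.0, 0], [0, 0, -1.0]])
    poses = {}
    bands = {}
    for i, (x, z) in enumerate([(-3, 10), (-1, 11), (0, 12), (1, 13), (2, 14), (3, 15)]):
        poses[f"c{i}"] = CameraPose(R=nadir, C=np.array([float(x), 0.0, float(z)]))
        bands[f"c{i}"] = "colour"
    for i, x in enumerate([-1.5, 1.5]):
        poses[f"n{i}"] = CameraPose(R=nadir, C=np.array([x, 0.5, 12.0]))
        bands[f"n{i}"] = "nir"
    model = truth_model(poses, {"colour": intr, "nir": intr}, bands)
    rng = np.random.default_rng(0)
    pts = np.column_stack([rng.uniform(-2, 2, 400), rng.uniform(-1.5, 1.5, 400),
                           np.zeros(400)])
    mesh = triangulate_surface(pts, outlier_filter=False)
    images = {}
    for iid, band in bands.items():
        shape = (120, 160, 3) if band == "colour" else (120, 160)
        images[iid] = np.full(shape, 0.5, dtype=np.float64)
    return model, mesh, images


@pytest.fixture(scope="module")
def flat_setup():
    return make_flat_setup()


class TestSelectViews:
    def test_best_four_by_distance(self, flat_setup):
        model, mesh, images = flat_setup
        assign = tx.select_views(mesh, model)
        # faces near the origin: nearest four colour cameras are c0..c3
        # (altitudes 10,11,12,13) for faces under the cameras
        centre_face = int(np.argmin(np.linalg.norm(mesh.face_centres[:, :2], axis=1)))
        ids = assign.images["colour"][centre_face]
        names = [assign.image_ids[i] for i in ids if i >= 0]
        assert len(names) == 4
        dists = {iid: np.linalg.norm(model.poses[iid].C - mesh.face_centres[centre_face])
                 for iid in model.poses if model.image_bands[iid] == "colour"}
        expected = sorted(dists, key=dists.get)[:4]
        assert set(names) == set(expected)

    def test_matches_brute_force_oracle_on_every_face(self, flat_setup):
        """Exact set equality against an all-pairs distance sort."""
        from shoremapper.geometry import project_points

        model, mesh, images = flat_setup
        assign = tx.select_views(mesh, model, zbuffer_bin_px=4)
        centres = mesh.face_centres
        band_imgs = sorted(i for i in model.poses if model.image_bands[i] == "colour")
        intr = model.intrinsics["colour"]
        mismatches = 0
        for f in range(centres.shape[0]):
            cands = []
            for iid in band_imgs:
                uv, z = project_points(centres[f][None], model.poses[iid], intr)
                if (z[0] > 0 and 0 <= uv[0, 0] <= intr.width - 1
                        and 0 <= uv[0, 1] <= intr.height - 1):
                    cands.append((np.linalg.norm(model.poses[iid].C - centres[f]), iid))
            cands.sort()
            expected = [iid for _, iid in cands[:4]]
            got = [assign.image_ids[i] for i in assign.images["colour"][f] if i >= 0]
            if set(got) != set(expected):
                mismatches += 1
        assert mismatches == 0

    def test_camera_behind_face_excluded(self):
        intr = CameraIntrinsics(200.0, 79.5, 59.5, width=160, height=120)
        nadir = np.array([[1.0, 0, 0], [0, -1.0, 0], [0, 0, -1.0]])
        up = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]])  # looking up
        poses = {"above": CameraPose(R=nadir, C=np.array([0.0, 0.0, 10.0])),
                 "below": CameraPose(R=up, C=np.array([0.0, 0.0, -10.0]))}
        bands = {"above": "colour", "below": "colour"}
        model = truth_model(poses, {"colour": intr}, bands)
        pts = np.array([[-1, -1, 0], [1, -1, 0], [1, 1, 0], [-1, 1, 0.0]])
        mesh = triangulate_surface(pts, outlier_filter=False)
        assign = tx.select_views(mesh, model, bands=("colour",))
        names = {assign.image_ids[i] for row in assign.images["colour"]
                 for i in row if i >= 0}
        assert names == {"above"}

    def test_weights_sum_to_one(self, flat_setup):
        model, mesh, images = flat_setup
        assign = tx.select_views(mesh, model)
        w = assign.weights["colour"]
        n = assign.n_sources("colour")
        assert np.allclose(w[n > 0].sum(axis=1), 1.0)


class TestBlending:
    def test_single_source_returns_that_sample(self, flat_setup):
        model, mesh, images = flat_setup
        imgs = {k: v.copy() for k, v in images.items()}
        imgs["c0"] = imgs["c0"] * 0 + 0.73
        assign = tx.select_views(mesh, model)
        # force single-source assignment on face 0
        assign.images["colour"][0, :] = -1
        assign.images["colour"][0, 0] = assign.image_ids.index("c0")
        assign.weights["colour"][0, :] = 0.0
        assign.weights["colour"][0, 0] = 1.0
        val = tx.blend_face(0, assign, imgs, model, mesh, band="colour")
        assert np.allclose(val[0], 0.73)

    def test_identical_sources_blend_to_same_value(self, flat_setup):
        model, mesh, images = flat_setup
        assign = tx.select_views(mesh, model)
        val = tx.blend_face(3, assign, images, model, mesh, band="colour")
        assert np.allclose(val[0], 0.5)

    def test_blend_is_convex_combination(self, flat_setup):
        model, mesh, images = flat_setup
        rng = np.random.default_rng(1)
        imgs = {k: (v + rng.uniform(0, 0.5)) for k, v in images.items()}
        assign = tx.select_views(mesh, model)
        lo = min(float(v.min()) for v in imgs.values())
        hi = max(float(v.max()) for v in imgs.values())
        pts = mesh.face_centres[:50]
        vals, _ = tx.blend_points(pts, np.arange(50), assign, imgs, model, "colour")
        ok = ~np.isnan(vals[:, 0])
        assert (vals[ok] >= lo - 1e-9).all()
        assert (vals[ok] <= hi + 1e-9).all()

    def test_uniform_albedo_mosaic_has_low_variation(self, flat_setup):
        """Blending must not create structure: CV < 2% on a uniform plane."""
        model, mesh, images = flat_setup
        assign = tx.select_views(mesh, model)
        mosaic = tx.render_orthomosaic(mesh, assign, images, model, cell_m=0.1)
        r = mosaic.bands["R"]
        vals = r.defined_values()
        assert vals.size > 100
        assert vals.std() / vals.mean() < 0.02


class TestWhiteBalance:
    def test_equal_inputs_equal_gains(self):
        g_red, g_nir = tx.white_balance_gains(
            {"red": 100.0, "nir": 100.0}, {"colour": 0.004, "nir": 0.004})
        assert g_red == g_nir

    def test_gain_ratio_follows_spectralon_ratio(self):
        g_red, g_nir = tx.white_balance_gains(
            {"red": 200.0, "nir": 100.0}, {"colour": 0.004, "nir": 0.004})
        assert np.isclose(g_nir / g_red, 2.0)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            tx.white_balance_gains({"red": 0.0, "nir": 1.0},
                                   {"colour": 0.004, "nir": 0.01})


class TestComputeNdvi:
    def _mosaic(self, R, N):
        return tx.OrthoMosaic(bands={
            "R": RasterGrid(np.asarray(R, dtype=float), (0.0, 0.0), 1.0, name="R"),
            "NIR": RasterGrid(np.asarray(N, dtype=float), (0.0, 0.0), 1.0, name="NIR"),
        })

    def test_equal_balanced_bands_give_zero(self):
        m = self._mosaic(np.full((4, 4), 2.0), np.full((4, 4), 1.0))
        out = tx.compute_ndvi(m, gains=(1.0, 2.0))
        assert np.allclose(out.grid.data, 0.0)

    def test_zero_nir_gives_minus_one(self):
        m = self._mosaic(np.full((3, 3), 1.0), np.zeros((3, 3)))
        out = tx.compute_ndvi(m, gains=(1.0, 1.0))
        assert np.allclose(out.grid.data, -1.0)

    def test_nodata_propagates(self):
        R = np.full((3, 3), 1.0)
        R[0, 0] = NODATA
        m = self._mosaic(R, np.full((3, 3), 1.0))
        out = tx.compute_ndvi(m, gains=(1.0, 1.0))
        assert out.grid.data[0, 0] == NODATA
        assert np.allclose(out.grid.data[1:], 0.0)

    def test_invariant_to_common_gain_scaling(self):
        rng = np.random.default_rng(2)
        R = rng.uniform(0.1, 1, (5, 5))
        N = rng.uniform(0.1, 1, (5, 5))
        a = tx.compute_ndvi(self._mosaic(R, N), gains=(1.3, 0.7)).grid.data
        b = tx.compute_ndvi(self._mosaic(R, N), gains=(13.0, 7.0)).grid.data
        assert np.allclose(a, b)
        assert (np.abs(a) <= 1.0).all()

    def test_flat_spectrum_scene_ndvi_zero(self, responses):
        """End-to-end white-balance property: flat reflectance -> NDVI 0."""
        from shoremapper.spectra import predict_band_response
        from shoremapper.synthetic import generate_scene
        from shoremapper.synthetic.render import (
            DEFAULT_EXPOSURES,
            spectralon_values,
        )

        scene = generate_scene(size_m=(20, 12), seed=3, n_classes=1,
                               flat_reflectance=0.5)
        # rendered band values of the flat surface
        r_val = (predict_band_response(scene.class_spectra["dry_rock"],
                                       responses["red"]).value
                 * DEFAULT_EXPOSURES["colour"])
        n_val = (predict_band_response(scene.class_spectra["dry_rock"],
                                       responses["nir"]).value
                 * DEFAULT_EXPOSURES["nir"])
        sv = spectralon_values(responses)
        gains = tx.white_balance_gains(
            {"red": sv["red"], "nir": sv["nir"]},
            {"colour": DEFAULT_EXPOSURES["colour"], "nir": DEFAULT_EXPOSURES["nir"]})
        m = self._mosaic(np.full((4, 4), r_val), np.full((4, 4), n_val))
        out = tx.compute_ndvi(m, gains)
        assert np.abs(out.grid.data).max() < 1e-6


class TestPatchStatistics:
    def _raster(self, data):
        return tx.NDVIRaster(
            grid=RasterGrid(np.asarray(data, dtype=float), (0.0, 0.0), 1.0),
            gains=(1.0, 1.0), exposures_s=(1.0, 1.0))

    def test_constant_raster_zero_sd(self):
        r = self._raster(np.full((40, 40), 0.42))
        patches = pd.DataFrame([{"label": "algae", "cx": 20, "cy": 20}])
        stats, table = tx.patch_statistics(r, patches)
        assert len(stats) == 1
        assert stats[0].mean == pytest.approx(0.42)
        assert stats[0].sd == 0.0
        assert stats[0].size_px == 15

    def test_patch_overlapping_nodata_excluded_with_warning(self):
        data = np.full((40, 40), 0.3)
        data[18, 18] = NODATA
        r = self._raster(data)
        patches = pd.DataFrame([{"label": "x", "cx": 20, "cy": 20},
                                {"label": "x", "cx": 30, "cy": 30}])
        with pytest.warns(UserWarning):
            stats, table = tx.patch_statistics(r, patches)
        assert len(stats) == 1

    def test_predicted_vs_measured_table(self):
        r = self._raster(np.full((40, 40), 0.5))
        patches = pd.DataFrame([{"label": "algae", "cx": 12, "cy": 12},
                                {"label": "algae", "cx": 28, "cy": 28}])
        _, table = tx.patch_statistics(r, patches, predicted={"algae": 0.55})
        row = table.iloc[0]
        assert row["n_patches"] == 2
        assert row["predicted"] == 0.55
        assert row["difference"] == pytest.approx(-0.05)
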