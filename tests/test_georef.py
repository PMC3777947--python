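import warnings

import numpy as np
import pytest
from scipy import optimize

from shoremapper.geodesy import GeodeticOrigin
from shoremapper.geometry import random_rotation, rodrigues
from shoremapper.georef import (
    DegenerateConfigurationError,
    GCPRecord,
    SimilarityTransform,
    adjust_vertical_datum,
    estimate_scale,
    georegister,
    horn_align,
)

ORIGIN = GeodeticOrigin(-35.0857, 150.6933, 0.0)


def make_gcps(true_enu, origin=ORIGIN, edge_m=2.0, gps_noise=0.0,
              recon_transform=None, seed=0):
    """GCP records from true ENU triad positions (3 per triad)."""
    rng = np.random.default_rng(seed)
    records = []
    for i, p in enumerate(true_enu):
        noisy = p + rng.normal(0, gps_noise, 3) if gps_noise > 0 else p
        lat, lon, alt = origin.enu_to_geodetic(noisy)
        rec = p if recon_transform is None else recon_transform.apply(p)
        records.append(GCPRecord(
            gcp_id=f"g{i}", triad_id=i // 3, lat_deg=float(lat),
            lon_deg=float(lon), alt_m=float(alt), edge_m=edge_m, recon_xyz=rec,
        ))
    return records


def equilateral_triads(n_triads=3, edge_m=2.0, seed=0):
    rng = np.random.default_rng(seed)
    pts = []
    r = edge_m / np.sqrt(3.0)
    for t in range(n_triads):
        c = np.array([rng.uniform(-20, 20), rng.uniform(-10, 10), rng.uniform(0, 2)])
        phase = rng.uniform(0, 2 * np.pi)
        R = random_rotation(rng)
        for k in range(3):
            ang = phase + 2 * np.pi * k / 3
            pts.append(c + R @ (r * np.array([np.cos(ang), np.sin(ang), 0.0])))
    return np.asarray(pts)


class TestEstimateScale:
    def test_single_triad_ratio(self):
        tri = equilateral_triads(1)  # edges exactly 2.0
        tf = SimilarityTransform(0.25, np.eye(3), np.zeros(3))
        gcps = make_gcps(tri, recon_transform=tf)  # reconstructed edges 0.5
        assert np.isclose(estimate_scale(gcps), 4.0, rtol=1e-12)

    def test_mean_over_triads(self):
        # two triads with per-edge ratios {4,4,4} and {2,2,2} -> mean 3
        tri1 = equilateral_triads(1, seed=1)
        tri2 = equilateral_triads(1, seed=2)
        g1 = make_gcps(tri1, recon_transform=SimilarityTransform(0.25, np.eye(3), np.zeros(3)))
        g2 = make_gcps(tri2, recon_transform=SimilarityTransform(0.5, np.eye(3), np.zeros(3)))
        for g in g2:
            g.triad_id = 1
            g.gcp_id += "_b"
        assert np.isclose(estimate_scale(g1 + g2), 3.0, rtol=1e-12)

    def test_synthetic_scene_scale_exact(self, mini_scene):
        from shoremapper.synthetic import place_gcps

        gcps, true_enu = place_gcps(mini_scene, n_triads=3, seed=5)
        rng = np.random.default_rng(3)
        tf = SimilarityTransform(1 / 6.3, random_rotation(rng), rng.normal(0, 4, 3))
        for g, p in zip(gcps, true_enu):
            g.recon_xyz = tf.apply(p)
        assert np.isclose(estimate_scale(gcps), 6.3, rtol=1e-6)

    def test_zero_length_edge_rejected(self):
        tri = equilateral_triads(1)
        gcps = make_gcps(tri)
        for g in gcps:
            g.recon_xyz = np.zeros(3)
        with pytest.raises(ValueError):
            estimate_scale(gcps)


class TestHornAlign:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(0, 5, (10, 3))
        tf, res = horn_align(pts, pts)
        assert np.allclose(tf.R, np.eye(3), atol=1e-12)
        assert np.abs(tf.t).max() < 1e-12
        assert res.max() < 1e-12

    def test_exact_recovery_of_random_similarities(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            src = rng.normal(0, 5, (8, 3))
            tf = SimilarityTransform(rng.uniform(0.2, 5.0), random_rotation(rng),
                                     rng.normal(0, 20, 3))
            est, res = horn_align(src, tf.apply(src), estimate_scale_flag=True)
            assert res.max() < 1e-9
            assert np.isclose(est.scale, tf.scale, rtol=1e-12)

    def test_three_point_residuals_match_rotation_grid_oracle(self):
        """Brute force: dense random rotation sampling + local refinement."""
        rng = np.random.default_rng(2)
        src = rng.normal(0, 2, (3, 3))
        dst = rng.normal(0, 2, (3, 3))
        tf, res = horn_align(src, dst)
        horn_cost = float((res**2).sum())

        c_src, c_dst = src.mean(0), dst.mean(0)

        def cost_of(R):
            d = (src - c_src) @ R.T + c_dst - dst
            return float((d**2).sum())

        best = np.inf
        best_v = None
        for _ in range(20000):
            R = random_rotation(rng)
            c = cost_of(R)
            if c < best:
                best, best_v = c, R
        # local polish of the best grid rotation
        from shoremapper.geometry import inverse_rodrigues

        v0 = inverse_rodrigues(best_v)
        sol = optimize.minimize(lambda v: cost_of(rodrigues(v)), v0,
                                method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-14})
        assert abs(np.sqrt(horn_cost) - np.sqrt(sol.fun)) < 1e-3
        assert horn_cost <= sol.fun + 1e-9  # Horn is the global optimum

    def test_returned_rotation_is_a_local_minimum(self):
        """No small random rotation perturbation reduces the residual."""
        rng = np.random.default_rng(3)
        src = rng.normal(0, 3, (6, 3))
        noise = rng.normal(0, 0.1, src.shape)
        dst = src @ random_rotation(rng).T + noise + 5.0
        tf, res = horn_align(src, dst)
        base = (res**2).sum()
        c_src, c_dst = src.mean(0), dst.mean(0)
        for _ in range(1000):
            ang = np.radians(rng.uniform(0, 5))
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            Rp = rodrigues(axis * ang) @ tf.R
            d = (src - c_src) @ Rp.T + c_dst - dst
            assert (d**2).sum() >= base - 1e-12

    def test_collinear_points_rejected(self):
        t = np.linspace(0, 1, 5)[:, None]
        src = t * np.array([1.0, 2.0, 3.0])
        with pytest.raises(DegenerateConfigurationError):
            horn_align(src, src + 1.0)

    def test_never_returns_a_reflection(self):
        rng = np.random.default_rng(4)
        src = rng.normal(0, 1, (4, 3))
        dst = src.copy()
        dst[:, 2] *= -1.0  # a reflection of the source
        tf, _ = horn_align(src, dst)
        assert np.linalg.det(tf.R) > 0


class TestSimilarityTransform:
    def test_inverse_roundtrip(self):
        rng = np.random.default_rng(5)
        tf = SimilarityTransform(3.3, random_rotation(rng), rng.normal(0, 5, 3))
        pts = rng.normal(0, 10, (50, 3))
        back = tf.inverse().apply(tf.apply(pts))
        assert np.abs(back - pts).max() < 1e-9

    def test_compose(self):
        rng = np.random.default_rng(6)
        a = SimilarityTransform(2.0, random_rotation(rng), rng.normal(0, 2, 3))
        b = SimilarityTransform(0.5, random_rotation(rng), rng.normal(0, 2, 3))
        pts = rng.normal(0, 3, (10, 3))
        assert np.allclose(a.compose(b).apply(pts), a.apply(b.apply(pts)))

    def test_scale_must_be_positive(self):
        with pytest.raises(ValueError):
            SimilarityTransform(-1.0, np.eye(3), np.zeros(3))


class TestGeoregister:
    def _setup(self, gps_noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        true_enu = equilateral_triads(3, seed=seed + 10)
        rec_tf = SimilarityTransform(1 / 5.7, random_rotation(rng),
                                     rng.normal(0, 3, 3))
        gcps = make_gcps(true_enu, gps_noise=gps_noise,
                         recon_transform=rec_tf, seed=seed)
        return gcps, true_enu, rec_tf

    def test_noiseless_residuals_below_1e6(self):
        gcps, _, _ = self._setup(gps_noise=0.0)
        tf, report = georegister(gcps, ORIGIN)
        assert report.global_residual_m < 1e-6
        assert report.local_residual_m < 1e-6
        assert np.isclose(tf.scale, 5.7, rtol=1e-9)

    def test_gps_noise_decouples_global_from_local(self):
        """Handheld-GPS noise inflates the global residual only: scale comes
        from tape-measured edges, so the local residual stays tiny."""
        globals_, locals_ = [], []
        for seed in range(5):
            gcps, _, _ = self._setup(gps_noise=1.2, seed=seed)
            _, report = georegister(gcps, ORIGIN)
            globals_.append(report.global_residual_m)
            locals_.append(report.local_residual_m)
        assert 0.4 < np.mean(globals_) < 3.0     # of order the GPS noise
        assert max(locals_) < 1e-6               # unaffected (exact recon)

    def test_report_has_global_and_local_fields(self):
        gcps, _, _ = self._setup()
        _, report = georegister(gcps, ORIGIN)
        d = report.to_dict()
        assert {"global_residual_m", "global_residual_2d_m",
                "local_residual_m"} <= set(d)


class TestVerticalDatum:
    def test_shift_down_to_datum(self):
        wl = np.column_stack([np.arange(10.0), np.zeros(10), np.full(10, 1.50)])
        pts = np.random.default_rng(0).normal(0, 3, (20, 3))
        shifted, dz = adjust_vertical_datum(pts, wl, 0.16)
        assert np.isclose(dz, -1.34)
        assert np.allclose(shifted[:, 2], pts[:, 2] - 1.34)
        assert np.allclose(shifted[:, :2], pts[:, :2])

    def test_already_correct_model_zero_shift(self):
        wl = np.column_stack([np.arange(5.0), np.zeros(5), np.full(5, 0.16)])
        _, dz = adjust_vertical_datum(np.zeros((3, 3)), wl, 0.16)
        assert abs(dz) < 1e-12

    def test_rigid_shift_preserves_pairwise_distances(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(0, 5, (30, 3))
        wl = rng.normal(0, 1, (10, 3))
        shifted, _ = adjust_vertical_datum(pts, wl, 0.16)
        d0 = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        d1 = np.linalg.norm(shifted[:, None] - shifted[None, :], axis=2)
        assert np.abs(d0 - d1).max() < 1e-9

    def test_empty_waterline_warns_and_noop(self):
        pts = np.ones((4, 3))
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            shifted, dz = adjust_vertical_datum(pts, np.zeros((0, 3)), 0.16)
        assert dz == 0.0
        assert any("waterline" in str(w.message) for w in rec)

    def test_transform_variant_composes_shift(self):
        tf = SimilarityTransform(2.0, np.eye(3), np.zeros(3))
        wl_enu = np.array([[0.0, 0.0, 1.0]])
        tf2, dz = adjust_vertical_datum(tf, wl_enu, 0.16)
        assert np.isclose(dz, -0.84)
        assert np.allclose(tf2.apply(np.zeros((1, 3))), [[0, 0, -0.84]])
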