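import numpy as np
import pytest

from shoremapper.spectra import default_camera_responses
from shoremapper.synthetic import generate_scene, plan_flight, render_views


@pytest.fixture(scope="session")
def responses():
    return default_camera_responses()


@pytest.fixture(scope="session")
def mini_scene():
    """Small intertidal scene shared by rendering-level tests."""
    return generate_scene(size_m=(40.0, 24.0), seed=11)


@pytest.fixture(scope="session")
def mini_render(mini_scene, responses):
    """Three colour views + two NIR views of the mini scene, with truth."""
    plan_c = plan_flight(mini_scene, altitude_m=15.0, overlap=0.5, seed=1, n_images=3)
    imgs_c, gt = render_views(mini_scene, plan_c, responses, seed=2)
    plan_n = plan_flight(mini_scene, altitude_m=16.0, overlap=0.5, seed=3,
                         band="nir", n_images=2, start_offset_m=1.5)
    imgs_n, gt = render_views(mini_scene, plan_n, responses, seed=4, ground_truth=gt)
    return imgs_c + imgs_n, gt


@pytest.fixture(scope="session")
def mini_features(mini_render):
    from shoremapper.features import extract_features

    imgs, _ = mini_render
    return {im.image_id: extract_features(im.luminance, im.image_id) for im in imgs}


def synthetic_track_model(
    n_views=8,
    n_points=400,
    noise_px=0.0,
    seed=0,
    focal=450.0,
    k1=-0.05,
    k2=0.01,
    altitude=15.0,
    extent=(24.0, 10.0),
    relief=0.6,
    two_bodies=False,
):
    """Track graph + keypoints from exact projections of random terrain points.

    The independent oracle for structure-from-motion: geometry is exact (or
    Gaussian-perturbed by ``noise_px``), with no detector in the loop.
    Returns (track_graph, keypoints, bands, true_poses, true_intrinsics, X).
    """
    from shoremapper.geometry import CameraIntrinsics, CameraPose, project_points, rodrigues
    from shoremapper.tracks import Track, TrackGraph

    rng = np.random.default_rng(seed)
    nadir = np.array([[1.0, 0, 0], [0, -1.0, 0], [0, 0, -1.0]])
    poses = {}
    bands = {}
    intr_c = CameraIntrinsics(focal, 319.5, 239.5, k1=k1, k2=k2,
                              width=640, height=480)
    intr_n = CameraIntrinsics(focal * 1.03, 319.5, 239.5, k1=k1 * 0.8, k2=k2,
                              width=640, height=480)
    xs = np.linspace(-extent[0] / 2, extent[0] / 2, n_views)
    for i, x in enumerate(xs):
        body = "nir" if (two_bodies and i % 3 == 2) else "colour"
        prefix = "n" if body == "nir" else "c"
        tilt = rodrigues(rng.normal(0, 0.03, 3))
        C = np.array([x, rng.normal(0, 1.0), altitude + rng.normal(0, 0.5)])
        poses[f"{prefix}{i:02d}"] = CameraPose(R=tilt @ nadir, C=C)
        bands[f"{prefix}{i:02d}"] = body
    X = np.column_stack([
        rng.uniform(-extent[0] / 2 - 5, extent[0] / 2 + 5, n_points),
        rng.uniform(-extent[1] / 2, extent[1] / 2, n_points),
        rng.uniform(-relief / 2, relief / 2, n_points),
    ])
    intr = {"colour": intr_c, "nir": intr_n}
    kps = {i: [] for i in poses}
    tracks = []
    for j in range(n_points):
        obs = {}
        for iid, pose in poses.items():
            uv, z = project_points(X[j][None], pose, intr[bands[iid]])
            u, v = uv[0]
            if z[0] > 0 and 0 <= u <= 639 and 0 <= v <= 479:
                obs[iid] = len(kps[iid])
                kps[iid].append(uv[0] + rng.normal(0, noise_px, 2))
        if len(obs) >= 2:
            tracks.append(Track(observations=obs,
                                bands=frozenset(bands[i] for i in obs)))
    tg = TrackGraph(tracks=tracks, image_bands=bands)
    kps = {k: np.asarray(v) for k, v in kps.items()}
    return tg, kps, bands, poses, intr, X


def true_pixel_mapping(gt, scene, image_a, image_b, kps):
    """Oracle: keypoints in image_a -> terrain -> pixels in image_b."""
    pose_a = gt.poses[image_a]
    intr_a = gt.intrinsics[gt.image_bands[image_a]]
    xn, yn = intr_a.pixel_to_normalized(kps[:, 0], kps[:, 1])
    d = np.column_stack([xn, yn, np.ones_like(xn)]) @ pose_a.R
    z = np.full(len(kps), float(np.mean(scene.heightfield)))
    for _ in range(40):
        t = (z - pose_a.C[2]) / d[:, 2]
        px = pose_a.C[0] + t * d[:, 0]
        py = pose_a.C[1] + t * d[:, 1]
        z = scene.elevation_at(px, py)
    X = np.column_stack([px, py, z])
    uv, _ = gt.project(image_b, X)
    return uv, X
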