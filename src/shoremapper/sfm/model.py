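"""Reconstruction container: poses, shared intrinsics, sparse/dense points.

Coordinates are arbitrary reconstruction units (scale-less, gauge fixed only
by the initial pair) until geo-registration maps them to ENU metres.  One
intrinsics block is shared per camera body ("colour", "nir"): the survey
cameras used fixed lenses and fixed exposure, so per-image intrinsics would
be under-constrained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ..geometry import CameraIntrinsics, CameraPose, project_points
from ..georef import SimilarityTransform
from ..tracks import TrackGraph


@dataclass
class ReconstructionModel:
    track_graph: TrackGraph
    keypoints: dict[str, np.ndarray]            # image id -> (N,2) pixel coords
    image_bands: dict[str, str]
    intrinsics: dict[str, CameraIntrinsics]
    poses: dict[str, CameraPose] = field(default_factory=dict)
    points: dict[int, np.ndarray] = field(default_factory=dict)   # track idx -> xyz
    dense_points: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    dense_bands: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype="U6"))
    registration_order: list[str] = field(default_factory=list)
    skipped_images: list[str] = field(default_factory=list)
    removed_obs: set = field(default_factory=set)   # {(track idx, image id)} pruned
    reprojection_rmse: float = np.nan

    # -- observations ------------------------------------------------------
    def track_observations(self, j: int) -> list[tuple[str, int]]:
        """Non-pruned (image id, keypoint) observations of track j."""
        return [
            (img, kp)
            for img, kp in self.track_graph.tracks[j].observations.items()
            if (j, img) not in self.removed_obs
        ]

    def observations(self) -> list[tuple[int, str, np.ndarray]]:
        """(track index, image id, observed uv) for every registered obs."""
        out = []
        for j in self.points:
            for img, kp in self.track_observations(j):
                if img in self.poses:
                    out.append((j, img, self.keypoints[img][kp]))
        return out

    def reprojection_errors(self) -> np.ndarray:
        errs = []
        for j, img, uv in self.observations():
            band = self.image_bands[img]
            proj, z = project_points(self.points[j][None, :], self.poses[img],
                                     self.intrinsics[band])
            errs.append(np.linalg.norm(proj[0] - uv))
        return np.asarray(errs)

    def update_rmse(self) -> float:
        e = self.reprojection_errors()
        self.reprojection_rmse = float(np.sqrt(np.mean(e**2))) if e.size else np.nan
        return self.reprojection_rmse

    @property
    def n_registered(self) -> int:
        return len(self.poses)

    def sparse_array(self) -> np.ndarray:
        if not self.points:
            return np.zeros((0, 3))
        return np.vstack([self.points[j] for j in sorted(self.points)])

    # -- transforms --------------------------------------------------------
    def apply_similarity(self, tf: SimilarityTransform) -> None:
        """Map the whole model (poses + points) through s R x + t in place."""
        for img, pose in list(self.poses.items()):
            self.poses[img] = CameraPose(R=pose.R @ tf.R.T, C=tf.apply(pose.C))
        for j in self.points:
            self.points[j] = tf.apply(self.points[j])
        if self.dense_points.size:
            self.dense_points = tf.apply(self.dense_points)

    # -- serialisation -----------------------------------------------------
    def to_json_dict(self) -> dict:
        return {
            "intrinsics": {b: k.to_dict() for b, k in self.intrinsics.items()},
            "poses": {i: p.to_dict() for i, p in self.poses.items()},
            "image_bands": self.image_bands,
            "registration_order": self.registration_order,
            "skipped_images": self.skipped_images,
            "reprojection_rmse": None if np.isnan(self.reprojection_rmse)
            else self.reprojection_rmse,
            "points": {str(j): X.tolist() for j, X in self.points.items()},
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh)

    def save_ply(self, path, dense: bool = False) -> None:
        import trimesh

        pts = self.dense_points if dense else self.sparse_array()
        trimesh.PointCloud(pts).export(str(path))
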