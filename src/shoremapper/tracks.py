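"""Chaining pairwise inlier matches into multi-image feature tracks.

A track is a connected component of the inlier match graph: the set of
(image, keypoint) observations of one physical 3D point.  Tracks containing
two keypoints from the same image are contradictory and dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .epipolar import PairMatches


@dataclass
class Track:
    observations: dict[str, int]     # image id -> keypoint index
    bands: frozenset[str] = frozenset()

    def __len__(self) -> int:
        return len(self.observations)


@dataclass
class TrackGraph:
    tracks: list[Track]
    image_bands: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.tracks)

    def band_coverage_counts(self) -> dict[str, int]:
        """Number of tracks seen only in colour, only in NIR, or in both."""
        counts = {"colour": 0, "nir": 0, "both": 0}
        for t in self.tracks:
            if len(t.bands) > 1:
                counts["both"] += 1
            elif t.bands:
                counts[next(iter(t.bands))] += 1
        return counts


class _UnionFind:
    def __init__(self):
        self.parent: dict = {}

    def find(self, x):
        root = x
        while self.parent.setdefault(root, root) != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def build_tracks(
    matches: list[PairMatches],
    image_bands: dict[str, str] | None = None,
    min_length: int = 2,
) -> TrackGraph:
    """Union-find over inlier matches; conflicting tracks are dropped."""
    uf = _UnionFind()
    for pm in matches:
        if pm.status != "matched":
            continue
        for ia, ib in pm.inlier_pairs():
            uf.union((pm.image_a, int(ia)), (pm.image_b, int(ib)))
    groups: dict = {}
    for node in list(uf.parent):
        groups.setdefault(uf.find(node), []).append(node)
    bands = image_bands or {}
    tracks = []
    for nodes in groups.values():
        if len(nodes) < min_length:
            continue
        obs: dict[str, int] = {}
        conflict = False
        for img, kp in nodes:
            if img in obs and obs[img] != kp:
                conflict = True
                break
            obs[img] = kp
        if conflict or len(obs) < min_length:
            continue
        track_bands = frozenset(bands.get(img, "colour") for img in obs)
        tracks.append(Track(observations=obs, bands=track_bands))
    # deterministic ordering: by (first image id, keypoint)
    tracks.sort(key=lambda t: sorted(t.observations.items()))
    return TrackGraph(tracks=tracks, image_bands=dict(bands))


def match_statistics(
    matches: list[PairMatches], image_bands: dict[str, str]
) -> pd.DataFrame:
    """Pairs matched and mean matches per pair, split by band combination.

    Mirrors the reporting structure of a field survey's match table
    (colour-colour / colour-NIR / NIR-NIR rows).
    """
    rows: dict[str, list[int]] = {}
    for pm in matches:
        if pm.status != "matched" or pm.n_inliers == 0:
            continue
        ba = image_bands.get(pm.image_a, "colour")
        bb = image_bands.get(pm.image_b, "colour")
        key = " to ".join(sorted([ba, bb]))
        rows.setdefault(key, []).append(pm.n_inliers)
    data = []
    for key in sorted(rows):
        vals = rows[key]
        data.append(
            {
                "band_pair": key,
                "n_matching_pairs": len(vals),
                "mean_matches_per_pair": float(np.mean(vals)),
            }
        )
    return pd.DataFrame(data)
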