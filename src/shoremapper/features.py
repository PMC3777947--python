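"""Local invariant features and pairwise descriptor matching.

SIFT features are detected on a luminance (or single-band) image; the same
descriptor works on colour and near-infrared frames, which is what lets the
two surveys be matched into one model: natural (here procedural) surface
texture produces similar gradient structure in both bands.

Pixel coordinate convention: origin at the centre of the top-left pixel,
x rightward, y downward, 0-based; keypoints are subpixel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.feature import SIFT


@dataclass
class FeatureSet:
    """Keypoints (x, y subpixel) and L2-normalised descriptors of one image."""

    image_id: str
    keypoints: np.ndarray        # (N, 2) float: x, y
    descriptors: np.ndarray      # (N, 128) float32, unit L2 norm
    scales: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __len__(self) -> int:
        return self.keypoints.shape[0]


def extract_features(
    image: np.ndarray,
    image_id: str = "",
    c_dog: float = 0.004,
    upsampling: int = 1,
    max_features: int | None = 4000,
) -> FeatureSet:
    """Detect SIFT features on a single-band or luminance-converted image.

    Deterministic for fixed input and settings.  A featureless (constant)
    image yields an empty set with a warning.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 3:
        img = img.mean(axis=2)
    rng_val = img.max() - img.min()
    if rng_val <= 0:
        warnings.warn(f"image {image_id!r} is constant: no features", stacklevel=2)
        return FeatureSet(image_id, np.zeros((0, 2)), np.zeros((0, 128), dtype=np.float32))
    img = (img - img.min()) / rng_val
    det = SIFT(upsampling=upsampling, c_dog=c_dog)
    try:
        det.detect_and_extract(img)
    except RuntimeError:
        warnings.warn(f"image {image_id!r}: SIFT found no keypoints", stacklevel=2)
        return FeatureSet(image_id, np.zeros((0, 2)), np.zeros((0, 128), dtype=np.float32))
    # positions are subpixel (row, col) -> (x, y)
    kp = det.positions[:, ::-1].astype(np.float64)
    desc = det.descriptors.astype(np.float32)
    norms = np.linalg.norm(desc, axis=1, keepdims=True)
    desc = desc / np.maximum(norms, 1e-12)
    scales = det.scales.astype(np.float64)
    if max_features is not None and kp.shape[0] > max_features:
        # keep the coarsest-to-finest deterministic subset by scale then y,x
        order = np.lexsort((kp[:, 0], kp[:, 1], -scales))[:max_features]
        order = np.sort(order)
        kp, desc, scales = kp[order], desc[order], scales[order]
    return FeatureSet(image_id, kp, desc, scales)


def match_pair(a: FeatureSet, b: FeatureSet, ratio: float = 0.8) -> np.ndarray:
    """Mutual nearest-neighbour candidates passing Lowe's ratio test.

    Returns an (M, 2) array of (index in a, index in b).  Symmetric: swapping
    the arguments permutes the columns.  ``ratio`` -> 0 gives no matches.
    """
    if len(a) == 0 or len(b) == 0:
        return np.zeros((0, 2), dtype=int)
    # descriptors are unit-norm: squared distance = 2 - 2 cos
    sim = a.descriptors @ b.descriptors.T
    d2 = np.maximum(2.0 - 2.0 * sim, 0.0)

    def best_two(dist: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if dist.shape[1] == 1:
            j = np.zeros(dist.shape[0], dtype=int)
            return j, dist[:, 0], np.full(dist.shape[0], np.inf)
        part = np.argpartition(dist, 1, axis=1)[:, :2]
        rows = np.arange(dist.shape[0])[:, None]
        two = dist[rows, part]
        order = np.argsort(two, axis=1)
        part = part[rows, order]
        two = two[rows, order]
        return part[:, 0], two[:, 0], two[:, 1]

    nn_ab, d1_ab, d2_ab = best_two(d2)
    nn_ba, d1_ba, d2_ba = best_two(d2.T)
    i = np.arange(len(a))
    mutual = nn_ba[nn_ab] == i
    with np.errstate(invalid="ignore"):
        ratio_ab = np.sqrt(d1_ab) < ratio * np.sqrt(d2_ab)
        ratio_ba = np.sqrt(d1_ba) < ratio * np.sqrt(d2_ba)
    # the ratio test is applied in both directions so that the result is
    # symmetric in the argument order
    keep = mutual & ratio_ab & ratio_ba[nn_ab]
    return np.column_stack([i[keep], nn_ab[keep]])
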