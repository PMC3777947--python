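"""Epipolar outlier rejection: RANSAC over the normalised 8-point algorithm.

Correct correspondences between two views of a rigid scene satisfy
x2^T F x1 = 0 for a rank-2 fundamental matrix F.  Candidate descriptor
matches are filtered by robustly estimating F and keeping matches whose
Sampson distance falls under a pixel threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PairMatches:
    """Filtered correspondences between one image pair."""

    image_a: str
    image_b: str
    pairs: np.ndarray          # (M, 2) candidate index pairs
    inliers: np.ndarray        # (M,) bool
    F: np.ndarray | None       # 3x3 rank-2, defined up to scale; None if unmatched
    status: str = "matched"    # "matched" | "unmatched"

    @property
    def n_inliers(self) -> int:
        return int(self.inliers.sum())

    def inlier_pairs(self) -> np.ndarray:
        return self.pairs[self.inliers]


def _hartley_normalization(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Similarity T so that T x has zero centroid and mean distance sqrt(2)."""
    c = x.mean(axis=0)
    d = np.linalg.norm(x - c, axis=1).mean()
    s = np.sqrt(2.0) / max(d, 1e-12)
    T = np.array([[s, 0.0, -s * c[0]], [0.0, s, -s * c[1]], [0.0, 0.0, 1.0]])
    xn = (x - c) * s
    return xn, T


def eight_point(x1: np.ndarray, x2: np.ndarray) -> np.ndarray | None:
    """Normalised 8-point estimate of F from >= 8 correspondences.

    Returns None for degenerate designs (rank-deficient constraint matrix).
    """
    if x1.shape[0] < 8:
        return None
    n1, T1 = _hartley_normalization(np.asarray(x1, dtype=float))
    n2, T2 = _hartley_normalization(np.asarray(x2, dtype=float))
    u1, v1 = n1[:, 0], n1[:, 1]
    u2, v2 = n2[:, 0], n2[:, 1]
    A = np.column_stack(
        [u2 * u1, u2 * v1, u2, v2 * u1, v2 * v1, v2, u1, v1, np.ones_like(u1)]
    )
    _, sv, Vt = np.linalg.svd(A)
    if sv[-2] < 1e-10 * max(sv[0], 1e-300):
        return None  # degenerate (e.g. collinear/coincident) configuration
    Fn = Vt[-1].reshape(3, 3)
    # enforce rank 2
    U, S, Vt2 = np.linalg.svd(Fn)
    Fn = U @ np.diag([S[0], S[1], 0.0]) @ Vt2
    F = T2.T @ Fn @ T1
    nrm = np.linalg.norm(F)
    return F / nrm if nrm > 0 else None


def sampson_distance(F: np.ndarray, x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """First-order geometric reprojection error, in pixels."""
    x1h = np.column_stack([x1, np.ones(x1.shape[0])])
    x2h = np.column_stack([x2, np.ones(x2.shape[0])])
    Fx1 = x1h @ F.T        # rows: F @ x1
    Ftx2 = x2h @ F         # rows: F^T @ x2
    num = np.einsum("ij,ij->i", x2h, Fx1) ** 2
    den = Fx1[:, 0] ** 2 + Fx1[:, 1] ** 2 + Ftx2[:, 0] ** 2 + Ftx2[:, 1] ** 2
    return np.sqrt(num / np.maximum(den, 1e-300))


def filter_epipolar(
    kp_a: np.ndarray,
    kp_b: np.ndarray,
    candidates: np.ndarray,
    threshold_px: float = 2.0,
    seed: int = 0,
    confidence: float = 0.999,
    max_iters: int = 2000,
    image_a: str = "a",
    image_b: str = "b",
) -> PairMatches:
    """RANSAC fundamental-matrix filtering of candidate matches.

    Deterministic given ``seed``.  Pairs with < 8 candidates, or whose
    configurations never yield a valid 8-point solution, are marked
    ``unmatched``.  The final F is re-estimated on all inliers.
    """
    candidates = np.asarray(candidates, dtype=int)
    m = candidates.shape[0]
    if m < 8:
        return PairMatches(image_a, image_b, candidates,
                           np.zeros(m, dtype=bool), None, status="unmatched")
    x1 = np.asarray(kp_a, dtype=float)[candidates[:, 0]]
    x2 = np.asarray(kp_b, dtype=float)[candidates[:, 1]]
    rng = np.random.default_rng(seed)

    best_inl: np.ndarray | None = None
    best_count = 0
    n_iters = max_iters
    it = 0
    while it < n_iters:
        it += 1
        idx = rng.choice(m, size=8, replace=False)
        F = eight_point(x1[idx], x2[idx])
        if F is None:
            continue
        d = sampson_distance(F, x1, x2)
        inl = d < threshold_px
        c = int(inl.sum())
        if c > best_count:
            best_count = c
            best_inl = inl
            # adaptive iteration count
            w = max(c / m, 1e-6)
            denom = np.log(max(1.0 - w**8, 1e-12))
            if denom < 0:
                need = np.log(1.0 - confidence) / denom
                n_iters = min(max_iters, int(np.ceil(min(need, max_iters))) + 1)
    if best_inl is None or best_count < 8:
        return PairMatches(image_a, image_b, candidates,
                           np.zeros(m, dtype=bool), None, status="unmatched")
    # refit on inliers, then re-classify (one guided iteration)
    for _ in range(2):
        F = eight_point(x1[best_inl], x2[best_inl])
        if F is None:
            break
        d = sampson_distance(F, x1, x2)
        new_inl = d < threshold_px
        if new_inl.sum() < 8:
            break
        best_inl = new_inl
    F_final = eight_point(x1[best_inl], x2[best_inl])
    if F_final is None:
        return PairMatches(image_a, image_b, candidates,
                           np.zeros(m, dtype=bool), None, status="unmatched")
    return PairMatches(image_a, image_b, candidates, best_inl, F_final)
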