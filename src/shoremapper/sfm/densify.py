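"""Dense reconstruction by two-view correlation on a pixel grid.

For every registered reference image, one candidate 3D point is sought per
``cell_px`` x ``cell_px`` pixel patch: the ray through the cell centre is
swept over the depth range spanned by the sparse points seen in that image,
each candidate depth is scored by zero-mean normalised cross-correlation
(ZNCC) of image patches in a partner view, the peak is refined to sub-sample
precision by parabolic interpolation, and the winning depth must be
confirmed by an independent narrow-band search in a *different* partner
view.  Cells whose projection leaves one partner fall back to the next
(several partners are ranked per reference image), so coverage degrades
gracefully towards the swath edges.  This is a deliberately simplified
two-view scheme standing in for full patch-expansion multi-view stereo; it
reaches the intended density regime (about one 3D feature per 5x5-pixel
patch) on well-textured scenes.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from ..geometry import project_points
from .model import ReconstructionModel

log = logging.getLogger(__name__)


def _luminance(img: np.ndarray) -> np.ndarray:
    return img.mean(axis=2) if img.ndim == 3 else img


def _sparse_depth_range(model: ReconstructionModel, image_id: str):
    pose = model.poses[image_id]
    X = [P for j, P in model.points.items()
         if image_id in model.track_graph.tracks[j].observations]
    if len(X) < 10:
        return None
    d = np.linalg.norm(np.asarray(X) - pose.C, axis=1)
    lo, hi = np.percentile(d, [1.0, 99.0])
    span = max(hi - lo, 0.02 * hi)
    lo = max(lo - 0.25 * span, 0.2 * np.median(d))  # stay strictly positive
    return lo, hi + 0.25 * span


def _select_partners(model: ReconstructionModel, image_id: str, depth_mid: float,
                     n_partners: int = 4) -> list[str]:
    """Partners with baseline/depth in a useful range, most covisible first."""
    pose = model.poses[image_id]
    covis: dict[str, int] = {}
    for j in model.points:
        obs = model.track_graph.tracks[j].observations
        if image_id in obs:
            for other in obs:
                if other != image_id and other in model.poses:
                    covis[other] = covis.get(other, 0) + 1
    scored = []
    for other, n in covis.items():
        b = np.linalg.norm(model.poses[other].C - pose.C)
        if 0.05 <= b / depth_mid <= 0.8:
            scored.append((n, other))
    scored.sort(reverse=True)
    return [img for _, img in scored[:n_partners]]


def densify(
    model: ReconstructionModel,
    images: dict[str, np.ndarray],
    cell_px: int = 5,
    patch_px: int = 7,
    zncc_min: float = 0.7,
    zncc_verify: float = 0.5,
    depth_samples: int = 40,
    consistency_rel: float = 0.01,
    bands: tuple[str, ...] = ("colour", "nir"),
    max_ref_images: int | None = None,
    chunk: int = 2048,
) -> dict:
    """Populate ``model.dense_points``; returns per-reference statistics.

    ``images`` maps image id to its pixel array (any band count; luminance
    is used for correlation).  Every accepted point has passed the primary
    ZNCC threshold in one partner *and* a depth-consistency check in a
    second; cells that cannot be verified in two views are dropped.
    """
    half = patch_px // 2
    refs = [i for i in model.registration_order
            if i in images and model.image_bands[i] in bands]
    if max_ref_images is not None:
        refs = refs[:max_ref_images]
    lum = {i: _luminance(np.asarray(images[i], dtype=np.float64))
           for i in model.poses if i in images}
    dy, dx = np.mgrid[-half:half + 1, -half:half + 1]
    dy = dy.ravel()
    dx = dx.ravel()

    all_pts, all_bands = [], []
    stats = {}
    for rid in refs:
        rng_d = _sparse_depth_range(model, rid)
        if rng_d is None:
            stats[rid] = {"cells": 0, "accepted": 0}
            continue
        d_lo, d_hi = rng_d
        partners = _select_partners(model, rid, 0.5 * (d_lo + d_hi))
        if len(partners) < 2:
            stats[rid] = {"cells": 0, "accepted": 0}
            log.info("densify: %s skipped (< 2 usable partner views)", rid)
            continue
        intr = model.intrinsics[model.image_bands[rid]]
        pose = model.poses[rid]
        ref = lum[rid]
        H, W = ref.shape

        u0 = np.arange(half + cell_px // 2, W - half, cell_px, dtype=float)
        v0 = np.arange(half + cell_px // 2, H - half, cell_px, dtype=float)
        uu, vv = np.meshgrid(u0, v0)
        uu, vv = uu.ravel(), vv.ravel()
        n_cells = uu.size
        xn, yn = intr.pixel_to_normalized(uu, vv)
        dirs = np.column_stack([xn, yn, np.ones_like(xn)]) @ pose.R
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)

        ref_patches = ref[(vv[:, None] + dy[None, :]).astype(int),
                          (uu[:, None] + dx[None, :]).astype(int)]
        rp = ref_patches - ref_patches.mean(axis=1, keepdims=True)
        rn = np.linalg.norm(rp, axis=1)
        valid_ref = rn > 1e-9
        rp = rp / np.maximum(rn, 1e-12)[:, None]

        depth_grid = 1.0 / np.linspace(1.0 / d_lo, 1.0 / d_hi, depth_samples)

        def search(partner_id, cells, d_grid):
            """Best ZNCC and refined depth per cell along the depth sweep."""
            p_pose = model.poses[partner_id]
            p_intr = model.intrinsics[model.image_bands[partner_id]]
            p_img = lum[partner_id]
            pH, pW = p_img.shape
            n_sel = cells.size
            D = d_grid.shape[1]
            best_s = np.full(n_sel, -np.inf)
            best_d = np.full(n_sel, np.nan)
            for s0 in range(0, n_sel, chunk):
                sl = slice(s0, min(s0 + chunk, n_sel))
                idx = cells[sl]
                Xc = (pose.C[None, None, :]
                      + d_grid[sl][:, :, None] * dirs[idx][:, None, :])
                uvp, z = project_points(Xc.reshape(-1, 3), p_pose, p_intr)
                u_s = uvp[:, 0][:, None] + dx[None, :]
                v_s = uvp[:, 1][:, None] + dy[None, :]
                inb = ((z > 0)
                       & (uvp[:, 0] > half) & (uvp[:, 0] < pW - half - 1)
                       & (uvp[:, 1] > half) & (uvp[:, 1] < pH - half - 1))
                samp = ndimage.map_coordinates(
                    p_img, [v_s.ravel(), u_s.ravel()], order=1, mode="nearest"
                ).reshape(-1, patch_px * patch_px)
                sp = samp - samp.mean(axis=1, keepdims=True)
                sp /= np.maximum(np.linalg.norm(sp, axis=1), 1e-12)[:, None]
                nsel = idx.size
                scores = np.einsum("cp,cdp->cd", rp[idx], sp.reshape(nsel, D, -1))
                scores[~inb.reshape(nsel, D)] = -np.inf
                scores[~valid_ref[idx], :] = -np.inf
                k = np.argmax(scores, axis=1)
                rows = np.arange(nsel)
                s_best = scores[rows, k]
                d_sel = d_grid[sl]
                d_ref = d_sel[rows, k].copy()
                km = np.clip(k, 1, D - 2)
                with np.errstate(invalid="ignore"):
                    s_m = scores[rows, km - 1]
                    s_p = scores[rows, km + 1]
                    denom = s_m - 2.0 * scores[rows, km] + s_p
                okd = ((k > 0) & (k < D - 1) & np.isfinite(s_best)
                       & np.isfinite(s_m) & np.isfinite(s_p)
                       & (np.abs(denom) > 1e-12))
                delta = np.zeros(nsel)
                delta[okd] = np.clip(
                    0.5 * (s_m[okd] - s_p[okd]) / denom[okd], -1.0, 1.0)
                step = np.zeros(nsel)
                step[okd] = (d_sel[rows, np.clip(km + 1, 0, D - 1)]
                             - d_sel[rows, np.clip(km - 1, 0, D - 1)])[okd] / 2.0
                best_s[sl] = s_best
                best_d[sl] = d_ref + delta * step
            return best_s, best_d

        # primary search: fall back to later partners for uncovered cells
        cells_all = np.arange(n_cells)
        s1 = np.full(n_cells, -np.inf)
        dd1 = np.full(n_cells, np.nan)
        used = np.full(n_cells, -1)
        pending = cells_all
        for p_i, pid in enumerate(partners):
            if pending.size == 0:
                break
            grid = np.broadcast_to(depth_grid, (pending.size, depth_samples)).copy()
            s, d = search(pid, pending, grid)
            got = np.isfinite(d) & (s > -np.inf)
            s1[pending[got]] = s[got]
            dd1[pending[got]] = d[got]
            used[pending[got]] = p_i
            pending = pending[~got]
        cand = np.isfinite(dd1) & (s1 >= zncc_min)

        # verification in a different partner (narrow band around the depth)
        verified = np.zeros(n_cells, dtype=bool)
        for p_i, pid in enumerate(partners):
            sel = np.flatnonzero(cand & ~verified & (used != p_i))
            if sel.size == 0:
                continue
            span = dd1[sel][:, None] * np.linspace(
                1.0 - 3.0 * consistency_rel, 1.0 + 3.0 * consistency_rel, 9)[None, :]
            s2, dd2 = search(pid, sel, span)
            with np.errstate(invalid="ignore"):
                agree = ((s2 >= zncc_verify)
                         & np.isfinite(dd2)
                         & (np.abs(dd2 - dd1[sel]) <= consistency_rel * dd1[sel]))
            verified[sel[agree]] = True
        cand &= verified

        pts = pose.C[None, :] + dd1[cand, None] * dirs[cand]
        all_pts.append(pts)
        all_bands.append(np.full(pts.shape[0], model.image_bands[rid], dtype="U6"))
        stats[rid] = {"cells": int(n_cells), "accepted": int(cand.sum())}
        log.info("densify %s: %d/%d cells accepted", rid, int(cand.sum()), n_cells)

    model.dense_points = np.vstack(all_pts) if all_pts else np.zeros((0, 3))
    model.dense_bands = (np.concatenate(all_bands) if all_bands
                         else np.zeros(0, dtype="U6"))
    accepted = sum(s["accepted"] for s in stats.values())
    cells = sum(s["cells"] for s in stats.values())
    return {
        "per_image": stats,
        "n_dense": int(accepted),
        "density_per_cell": accepted / cells if cells else 0.0,
    }
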