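"""Sparse bundle adjustment.

Joint nonlinear least squares over all registered camera poses, the camera
bodies' shared intrinsics (focal + two radial distortion terms; principal
point held at the sensor centre) and all 3D points, minimising
Huber-robustified reprojection error.

Solver: Levenberg-Marquardt with the Schur complement.  The normal
equations are reduced onto the camera/intrinsics block (a few hundred
parameters regardless of the number of points) by eliminating the
block-diagonal point Hessian, so every LM step is solved exactly; the
robust loss enters through iteratively reweighted least squares.  Rotations
are parametrised as axis-angle with the closed-form SO(3) left Jacobian.

Gauge: the first registered camera's pose is held fixed; the global scale
remains free (it is fixed later by geo-registration).

A known failure mode of self-calibrating near-planar, near-nadir surveys is
a shallow spurious minimum along the focal-length/flying-height ambiguity:
``focal_sweep_refine`` walks that one-dimensional valley explicitly with
compensated warm starts and keeps the lowest-cost solution.
"""

from __future__ import annotations

import logging

import numpy as np

from ..geometry import CameraIntrinsics, CameraPose, inverse_rodrigues, rodrigues, skew
from .model import ReconstructionModel

log = logging.getLogger(__name__)


class BundleDivergenceError(RuntimeError):
    pass


def left_jacobian_so3(v: np.ndarray) -> np.ndarray:
    """Left Jacobian of SO(3): exp(v + d) ~= exp(J_l(v) d) exp(v)."""
    theta = np.linalg.norm(v)
    K = skew(v)
    if theta < 1e-8:
        return np.eye(3) + 0.5 * K
    return (
        np.eye(3)
        + (1.0 - np.cos(theta)) / theta**2 * K
        + (theta - np.sin(theta)) / theta**3 * (K @ K)
    )


def _gather_observations(model: ReconstructionModel):
    images = [i for i in model.registration_order if i in model.poses]
    img_index = {im: k for k, im in enumerate(images)}
    bands = sorted({model.image_bands[i] for i in images})
    band_index = {b: k for k, b in enumerate(bands)}
    pt_ids = sorted(model.points)
    pt_index = {j: k for k, j in enumerate(pt_ids)}
    cam_of, pt_of, band_of, uv = [], [], [], []
    for j in pt_ids:
        for img, kp in model.track_observations(j):
            if img not in img_index:
                continue
            cam_of.append(img_index[img])
            pt_of.append(pt_index[j])
            band_of.append(band_index[model.image_bands[img]])
            uv.append(model.keypoints[img][kp])
    order = np.lexsort((np.asarray(cam_of), np.asarray(pt_of)))  # group by point
    return (
        images, bands, pt_ids,
        np.asarray(cam_of)[order], np.asarray(pt_of)[order],
        np.asarray(band_of)[order], np.asarray(uv, dtype=float)[order],
    )


class _BundleProblem:
    """Parameter packing and analytic residual/Jacobian-block evaluation."""

    def __init__(self, model: ReconstructionModel, fix_gauge: bool,
                 optimize_intrinsics: bool,
                 intrinsics_prior: dict | None = None,
                 focal_prior_sigma_rel: float | None = None,
                 distortion_prior_sigma: float = 0.15):
        (self.images, self.bands, self.pt_ids, self.cam_of, self.pt_of,
         self.band_of, self.uv) = _gather_observations(model)
        self.ncams = len(self.images)
        self.nbands = len(self.bands)
        self.npts = len(self.pt_ids)
        self.nobs = self.uv.shape[0]
        self.fix_gauge = fix_gauge
        self.optimize_intrinsics = optimize_intrinsics
        self.model = model
        intr0 = {b: model.intrinsics[b] for b in self.bands}
        self.cx = np.array([intr0[b].cx for b in self.bands])
        self.cy = np.array([intr0[b].cy for b in self.bands])
        self.f_fixed = np.array([intr0[b].focal for b in self.bands])
        self.k1_fixed = np.array([intr0[b].k1 for b in self.bands])
        self.k2_fixed = np.array([intr0[b].k2 for b in self.bands])
        # u-block layout: 6 per camera (fixed camera zeroed) + 3 per band
        self.nu = 6 * self.ncams + (3 * self.nbands if optimize_intrinsics else 0)
        # optional weak Gaussian prior on the shared intrinsics (off by
        # default): available for surveys whose geometry barely constrains
        # the self-calibration, at the cost of a small bias along the
        # focal/distortion ambiguity valley
        self.use_prior = focal_prior_sigma_rel is not None
        if intrinsics_prior is None:
            intrinsics_prior = {b: model.intrinsics[b].focal for b in self.bands}
        self.f_prior = np.array([float(intrinsics_prior.get(b, self.f_fixed[i]))
                                 for i, b in enumerate(self.bands)])
        self.f_sigma = (focal_prior_sigma_rel or 1.0) * self.f_prior
        self.k_sigma = distortion_prior_sigma

    def prior_cost(self, x: np.ndarray) -> float:
        if not self.optimize_intrinsics or not self.use_prior:
            return 0.0
        _, _, _, f, k1, k2, _ = self.unpack(x)
        c = 0.5 * np.sum(((f - self.f_prior) / self.f_sigma) ** 2)
        c += 0.5 * np.sum((k1 / self.k_sigma) ** 2)
        c += 0.5 * np.sum((k2 / self.k_sigma) ** 2)
        return float(c)

    # -- state vector ------------------------------------------------------
    def pack(self) -> np.ndarray:
        x = []
        for img in self.images:
            p = self.model.poses[img]
            x.extend(inverse_rodrigues(p.R))
            x.extend(p.C)
        if self.optimize_intrinsics:
            for b in self.bands:
                k = self.model.intrinsics[b]
                x.extend([k.focal, k.k1, k.k2])
        pts = np.vstack([self.model.points[j] for j in self.pt_ids])
        return np.concatenate([np.asarray(x), pts.ravel()])

    def unpack(self, x: np.ndarray):
        Rs, Cs, vs = [], [], []
        for c in range(self.ncams):
            v = x[6 * c:6 * c + 3]
            Rs.append(rodrigues(v))
            Cs.append(x[6 * c + 3:6 * c + 6])
            vs.append(v)
        off = 6 * self.ncams
        if self.optimize_intrinsics:
            kb = x[off:off + 3 * self.nbands].reshape(self.nbands, 3)
            f, k1, k2 = kb[:, 0].copy(), kb[:, 1].copy(), kb[:, 2].copy()
            off += 3 * self.nbands
        else:
            f, k1, k2 = self.f_fixed, self.k1_fixed, self.k2_fixed
        X = x[off:].reshape(self.npts, 3)
        return Rs, Cs, vs, f, k1, k2, X

    def write_back(self, x: np.ndarray) -> None:
        Rs, Cs, _, f, k1, k2, X = self.unpack(x)
        start = 1 if self.fix_gauge else 0
        for c in range(start, self.ncams):
            self.model.poses[self.images[c]] = CameraPose(R=Rs[c], C=Cs[c])
        if self.optimize_intrinsics:
            for bi, b in enumerate(self.bands):
                old = self.model.intrinsics[b]
                self.model.intrinsics[b] = CameraIntrinsics(
                    focal=float(f[bi]), cx=old.cx, cy=old.cy,
                    k1=float(k1[bi]), k2=float(k2[bi]),
                    width=old.width, height=old.height,
                )
        for k, j in enumerate(self.pt_ids):
            self.model.points[j] = X[k].copy()

    # -- evaluation --------------------------------------------------------
    def residuals(self, x: np.ndarray) -> np.ndarray:
        """(nobs, 2) reprojection residuals."""
        Rs, Cs, _, f, k1, k2, X = self.unpack(x)
        Xc = np.empty((self.nobs, 3))
        for c in range(self.ncams):
            m = self.cam_of == c
            if not m.any():
                continue
            Xc[m] = (X[self.pt_of[m]] - Cs[c]) @ Rs[c].T
        z = np.where(np.abs(Xc[:, 2]) < 1e-12, 1e-12, Xc[:, 2])
        xn = Xc[:, 0] / z
        yn = Xc[:, 1] / z
        r2 = xn * xn + yn * yn
        bo = self.band_of
        d = 1.0 + k1[bo] * r2 + k2[bo] * r2 * r2
        u = f[bo] * xn * d + self.cx[bo]
        v = f[bo] * yn * d + self.cy[bo]
        return np.column_stack([u - self.uv[:, 0], v - self.uv[:, 1]])

    def blocks(self, x: np.ndarray):
        """Residuals + analytic per-observation Jacobian blocks.

        Returns r (nobs,2), Jc (nobs,2,6), Jk (nobs,2,3), Jp (nobs,2,3).
        The gauge-fixed camera's Jc rows are zero.
        """
        Rs, Cs, vs, f, k1, k2, X = self.unpack(x)
        n = self.nobs
        r = np.empty((n, 2))
        Jc = np.zeros((n, 2, 6))
        Jk = np.zeros((n, 2, 3))
        Jp = np.zeros((n, 2, 3))
        for c in range(self.ncams):
            m = self.cam_of == c
            if not m.any():
                continue
            pts = self.pt_of[m]
            bnd = self.band_of[m]
            q = X[pts] - Cs[c]
            p = q @ Rs[c].T
            z = np.where(np.abs(p[:, 2]) < 1e-12, 1e-12, p[:, 2])
            xn = p[:, 0] / z
            yn = p[:, 1] / z
            r2 = xn * xn + yn * yn
            fb, k1b, k2b = f[bnd], k1[bnd], k2[bnd]
            dd = 1.0 + k1b * r2 + k2b * r2 * r2
            r[m, 0] = fb * xn * dd + self.cx[bnd] - self.uv[m, 0]
            r[m, 1] = fb * yn * dd + self.cy[bnd] - self.uv[m, 1]
            a = k1b + 2.0 * k2b * r2
            B = np.empty((m.sum(), 2, 2))
            B[:, 0, 0] = fb * (dd + 2.0 * xn * xn * a)
            B[:, 0, 1] = fb * 2.0 * xn * yn * a
            B[:, 1, 0] = B[:, 0, 1]
            B[:, 1, 1] = fb * (dd + 2.0 * yn * yn * a)
            G = np.zeros((m.sum(), 2, 3))
            G[:, 0, 0] = 1.0 / z
            G[:, 0, 2] = -xn / z
            G[:, 1, 1] = 1.0 / z
            G[:, 1, 2] = -yn / z
            A = np.einsum("nij,njk->nik", B, G)
            Jp[m] = np.einsum("nik,kl->nil", A, Rs[c])
            if not (self.fix_gauge and c == 0):
                Jl = left_jacobian_so3(vs[c])
                Pskew = np.zeros((m.sum(), 3, 3))
                Pskew[:, 0, 1] = -p[:, 2]
                Pskew[:, 0, 2] = p[:, 1]
                Pskew[:, 1, 0] = p[:, 2]
                Pskew[:, 1, 2] = -p[:, 0]
                Pskew[:, 2, 0] = -p[:, 1]
                Pskew[:, 2, 1] = p[:, 0]
                dpdv = -np.einsum("nij,jk->nik", Pskew, Jl)
                Jc[m, :, :3] = np.einsum("nik,nkl->nil", A, dpdv)
                Jc[m, :, 3:] = -Jp[m]
            if self.optimize_intrinsics:
                Jk[m, 0, 0] = xn * dd
                Jk[m, 1, 0] = yn * dd
                Jk[m, 0, 1] = fb * xn * r2
                Jk[m, 1, 1] = fb * yn * r2
                Jk[m, 0, 2] = fb * xn * r2 * r2
                Jk[m, 1, 2] = fb * yn * r2 * r2
        return r, Jc, Jk, Jp

    def sparse_jacobian(self, x: np.ndarray):
        """Assemble the full sparse Jacobian (testing / diagnostics)."""
        from scipy.sparse import csr_matrix

        r, Jc, Jk, Jp = self.blocks(x)
        rows, cols, data = [], [], []
        idx = np.arange(self.nobs)
        for row in (0, 1):
            rr = 2 * idx + row
            rows += [np.repeat(rr, 6)]
            cols += [(6 * self.cam_of[:, None] + np.arange(6)[None, :]).ravel()]
            data += [Jc[:, row, :].ravel()]
            if self.optimize_intrinsics:
                off = 6 * self.ncams
                rows += [np.repeat(rr, 3)]
                cols += [(off + 3 * self.band_of[:, None] + np.arange(3)[None, :]).ravel()]
                data += [Jk[:, row, :].ravel()]
            off = self.nu
            rows += [np.repeat(rr, 3)]
            cols += [(off + 3 * self.pt_of[:, None] + np.arange(3)[None, :]).ravel()]
            data += [Jp[:, row, :].ravel()]
        nparams = self.nu + 3 * self.npts
        return csr_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=(2 * self.nobs, nparams),
        )


def _huber_weights(r: np.ndarray, delta: float) -> tuple[np.ndarray, float]:
    e = np.linalg.norm(r, axis=1)
    w = np.where(e <= delta, 1.0, delta / np.maximum(e, 1e-300))
    cost = float(np.where(e <= delta, 0.5 * e**2, delta * (e - 0.5 * delta)).sum())
    return w, cost


def _schur_lm(
    prob: _BundleProblem,
    x0: np.ndarray,
    huber_px: float,
    max_iters: int,
    ftol: float,
    lam0: float = 1e-4,
) -> tuple[np.ndarray, dict]:
    """Levenberg-Marquardt with point-block elimination (Schur complement)."""
    nu, npts, nobs = prob.nu, prob.npts, prob.nobs
    x = x0.copy()
    lam = lam0
    r, Jc, Jk, Jp = prob.blocks(x)
    w, cost = _huber_weights(r, huber_px)
    cost += prob.prior_cost(x)
    n_iter = 0
    # u-column index of each observation's camera / band block
    cam_cols = 6 * prob.cam_of
    band_cols = 6 * prob.ncams + 3 * prob.band_of if prob.optimize_intrinsics else None
    # pairs of observations of the same point (for the Schur correction)
    counts = np.bincount(prob.pt_of, minlength=npts)
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    pair_i, pair_j = [], []
    for k in np.unique(counts):
        if k == 0:
            continue
        sel = np.flatnonzero(counts == k)
        base = starts[sel]
        offs = np.arange(k)
        ii = (base[:, None, None] + offs[None, :, None] + np.zeros((1, 1, k), int)).ravel()
        jj = (base[:, None, None] + np.zeros((1, k, 1), int) + offs[None, None, :]).ravel()
        pair_i.append(ii)
        pair_j.append(jj)
    pair_i = np.concatenate(pair_i)
    pair_j = np.concatenate(pair_j)

    # per-observation u-column indices (camera 6 cols [+ band 3 cols])
    if prob.optimize_intrinsics:
        colidx = np.concatenate(
            [cam_cols[:, None] + np.arange(6)[None, :],
             band_cols[:, None] + np.arange(3)[None, :]], axis=1,
        )
    else:
        colidx = cam_cols[:, None] + np.arange(6)[None, :]
    # composite (camera, band) key: observations sharing it share colidx rows
    key = prob.cam_of * (prob.nbands + 1) + prob.band_of
    nkey = prob.ncams * (prob.nbands + 1)

    stale_blocks = False
    while n_iter < max_iters:
        n_iter += 1
        if stale_blocks:
            r, Jc, Jk, Jp = prob.blocks(x)
            stale_blocks = False
        sw = np.sqrt(w)
        Bu = (np.concatenate([Jc, Jk], axis=2) if prob.optimize_intrinsics else Jc) \
            * sw[:, None, None]
        Bp = Jp * sw[:, None, None]
        rw = r * sw[:, None]

        # point Hessian blocks and gradients
        App = np.zeros((npts, 3, 3))
        np.add.at(App, prob.pt_of, np.einsum("nij,nik->njk", Bp, Bp))
        gp = np.zeros((npts, 3))
        np.add.at(gp, prob.pt_of, np.einsum("nij,ni->nj", Bp, rw))
        App_d = App.copy()
        diag = np.einsum("nkk->nk", App)
        for k in range(3):
            App_d[:, k, k] += lam * np.maximum(diag[:, k], 1e-12)
        Ainv = np.linalg.inv(App_d)

        # u-block Hessian and gradient, segment-summed by (camera, band)
        S = np.zeros((nu, nu))
        gu = np.zeros(nu)
        HuuB = np.einsum("nij,nik->njk", Bu, Bu)
        guB = np.einsum("nij,ni->nj", Bu, rw)
        order = np.argsort(key, kind="stable")
        cuts = np.concatenate([[0], np.flatnonzero(np.diff(key[order])) + 1])
        Hsum = np.add.reduceat(HuuB[order], cuts, axis=0)
        gsum = np.add.reduceat(guB[order], cuts, axis=0)
        rep = order[cuts]
        for t in range(rep.size):
            ci = colidx[rep[t]]
            S[np.ix_(ci, ci)] += Hsum[t]
            gu[ci] += gsum[t]

        # Schur complement: S -= sum_p W_p A_p^-1 W_p^T over same-point pairs
        C = np.einsum("nji,njk->nik", Bu, Bp)                   # (n, nb, 3)
        Ti = np.einsum("nik,nkl->nil", C, Ainv[prob.pt_of])     # C A^-1
        pair_blocks = np.einsum("pik,pjk->pij", Ti[pair_i], C[pair_j])
        key2 = key[pair_i].astype(np.int64) * nkey + key[pair_j]
        order2 = np.argsort(key2, kind="stable")
        cuts2 = np.concatenate([[0], np.flatnonzero(np.diff(key2[order2])) + 1])
        Bsum = np.add.reduceat(pair_blocks[order2], cuts2, axis=0)
        rep2 = order2[cuts2]
        for t in range(rep2.size):
            S[np.ix_(colidx[pair_i[rep2[t]]], colidx[pair_j[rep2[t]]])] -= Bsum[t]

        # reduced gradient: gu - sum_p W_p A_p^-1 gp_p
        Agp = np.einsum("nkl,nl->nk", Ainv, gp)
        gu_red = gu - np.bincount(
            colidx.ravel(),
            weights=np.einsum("nik,nk->ni", C, Agp[prob.pt_of]).ravel(),
            minlength=nu,
        )

        # intrinsics prior (Gauss-Newton exact: quadratic terms)
        if prob.optimize_intrinsics and prob.use_prior:
            _, _, _, f_cur, k1_cur, k2_cur, _ = prob.unpack(x)
            for bi in range(prob.nbands):
                base = 6 * prob.ncams + 3 * bi
                S[base, base] += 1.0 / prob.f_sigma[bi] ** 2
                gu_red[base] += (f_cur[bi] - prob.f_prior[bi]) / prob.f_sigma[bi] ** 2
                for kk, val in ((1, k1_cur[bi]), (2, k2_cur[bi])):
                    S[base + kk, base + kk] += 1.0 / prob.k_sigma ** 2
                    gu_red[base + kk] += val / prob.k_sigma ** 2

        Sd = S.copy()
        Sd[np.diag_indices(nu)] += lam * np.maximum(np.diag(S), 1e-12)
        if prob.fix_gauge:
            Sd[:6, :] = 0.0
            Sd[:, :6] = 0.0
            Sd[np.arange(6), np.arange(6)] = 1.0
            gu_red[:6] = 0.0
        try:
            du = np.linalg.solve(Sd, -gu_red)
        except np.linalg.LinAlgError:
            lam *= 10.0
            continue
        # back-substitute point updates: dp = -A^-1 (gp + W^T du)
        cross = np.zeros((npts, 3))
        np.add.at(cross, prob.pt_of, np.einsum("nki,nk->ni", C, du[colidx]))
        dp = -np.einsum("nkl,nl->nk", Ainv, gp + cross)

        x_new = x.copy()
        x_new[:nu] += du
        x_new[nu:] += dp.ravel()
        r_new = prob.residuals(x_new)
        w_new, cost_new = _huber_weights(r_new, huber_px)
        cost_new += prob.prior_cost(x_new)
        if cost_new < cost:
            rel = (cost - cost_new) / max(cost, 1e-300)
            x = x_new
            w, cost = w_new, cost_new
            lam = max(lam / 3.0, 1e-10)
            stale_blocks = True
            if rel < ftol:
                break
        else:
            lam *= 4.0
            if lam > 1e8:
                break
    return x, {"cost": cost, "n_iter": n_iter, "lambda": lam}


def bundle_adjust(
    model: ReconstructionModel,
    fix_gauge: bool = True,
    huber_px: float = 2.0,
    optimize_intrinsics: bool = True,
    ftol: float = 1e-8,
    max_iters: int = 100,
    intrinsics_prior: dict | None = None,
    focal_prior_sigma_rel: float | None = None,
    **_legacy,
) -> dict:
    """Refine the model in place; returns a fit-info dict.

    The robust objective is non-increasing: LM only ever accepts decreasing
    steps, and if no acceptable step exists the model is left at its input
    state (an actual increase would raise :class:`BundleDivergenceError`).
    """
    if model.n_registered < 2:
        raise ValueError("bundle adjustment needs >= 2 registered views")
    prob = _BundleProblem(model, fix_gauge, optimize_intrinsics,
                          intrinsics_prior=intrinsics_prior,
                          focal_prior_sigma_rel=focal_prior_sigma_rel)
    x0 = prob.pack()
    r0 = prob.residuals(x0)
    _, cost0 = _huber_weights(r0, huber_px)
    cost0 += prob.prior_cost(x0)
    x, info = _schur_lm(prob, x0, huber_px, max_iters, ftol)
    if info["cost"] > cost0 * (1.0 + 1e-12):
        raise BundleDivergenceError(
            f"bundle adjustment increased the objective ({cost0:.6g} -> {info['cost']:.6g})"
        )
    prob.write_back(x)
    rmse = model.update_rmse()
    return {
        "cost_before": cost0, "cost_after": info["cost"], "n_iter": info["n_iter"],
        "n_obs": prob.nobs, "n_points": prob.npts, "n_cams": prob.ncams,
        "rmse_px": rmse,
    }


def focal_sweep_refine(
    model: ReconstructionModel,
    scales: tuple[float, ...] = (0.95, 1.0, 1.05),
    huber_px: float = 2.0,
    max_iters: int = 60,
    intrinsics_prior: dict | None = None,
) -> dict:
    """Escape the focal/flying-height ambiguity by a compensated 1-D sweep.

    For each candidate scale the focal lengths are multiplied by ``s`` and
    every camera centre is stretched away from the median point elevation by
    the same factor (the compensating motion for a quasi-planar scene), then
    the model is re-bundled; the lowest-cost solution wins.
    """
    import copy

    best = None
    for s in scales:
        m = copy.deepcopy(model)
        if s != 1.0:
            zref = float(np.median(m.sparse_array()[:, 2]))
            for b in m.intrinsics:
                k = m.intrinsics[b]
                m.intrinsics[b] = CameraIntrinsics(
                    k.focal * s, k.cx, k.cy, k1=k.k1, k2=k.k2,
                    width=k.width, height=k.height,
                )
            for img, pose in list(m.poses.items()):
                C = pose.C.copy()
                C[2] = zref + s * (C[2] - zref)
                m.poses[img] = CameraPose(R=pose.R, C=C)
        info = bundle_adjust(m, huber_px=huber_px, max_iters=max_iters, ftol=1e-10,
                             intrinsics_prior=intrinsics_prior)
        log.info("focal sweep s=%.3f: cost %.1f rmse %.4f focal %s",
                 s, info["cost_after"], info["rmse_px"],
                 {b: round(m.intrinsics[b].focal, 1) for b in m.intrinsics})
        if best is None or info["cost_after"] < best[0]:
            best = (info["cost_after"], s, m, info)
    _, s_best, m_best, info = best
    model.poses.update(m_best.poses)
    model.intrinsics.update(m_best.intrinsics)
    model.points.update(m_best.points)
    model.update_rmse()
    info["best_scale"] = s_best
    return info
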