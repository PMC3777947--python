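"""Ground-truth-driven annotations for synthetic surveys.

In a field survey, GCP panels and the waterline are identified by hand in
the pointcloud (reconstruction coordinates).  For synthetic scenes the same
annotations are generated from ground truth: the true ENU positions are
mapped through the gauge similarity that relates the true world to the
arbitrary reconstruction frame (fitted on camera centres).
"""

from __future__ import annotations

import numpy as np

from ..georef import GCPRecord, SimilarityTransform, horn_align
from ..sfm.model import ReconstructionModel
from .render import GroundTruth


def gauge_transform(model: ReconstructionModel, gt: GroundTruth) -> SimilarityTransform:
    """Similarity mapping reconstruction coordinates to true ENU, fitted on
    the camera centres of all registered images (least squares, with scale)."""
    reg = [i for i in model.registration_order if i in gt.poses]
    if len(reg) < 3:
        raise ValueError("need >= 3 registered images with ground truth")
    C_rec = np.array([model.poses[i].C for i in reg])
    C_true = np.array([gt.poses[i].C for i in reg])
    tf, _ = horn_align(C_rec, C_true, estimate_scale_flag=True)
    return tf


def annotate_gcps(
    model: ReconstructionModel,
    gt: GroundTruth,
    gcps: list[GCPRecord],
    true_enu: np.ndarray,
    annotation_noise_m: float = 0.0,
    seed: int = 0,
) -> SimilarityTransform:
    """Attach reconstruction-frame positions to GCP records.

    ``annotation_noise_m`` adds identification jitter (in metres, true
    scale) emulating imperfect manual clicking.  Returns the ENU->recon
    transform used.
    """
    enu_to_rec = gauge_transform(model, gt).inverse()
    rng = np.random.default_rng((seed, 424243))
    pos = np.asarray(true_enu, dtype=float)
    if annotation_noise_m > 0:
        pos = pos + rng.normal(0.0, annotation_noise_m, size=pos.shape)
    rec = enu_to_rec.apply(pos)
    for g, p in zip(gcps, rec):
        g.recon_xyz = p
    return enu_to_rec


def waterline_in_reconstruction(
    model: ReconstructionModel, gt: GroundTruth, waterline_enu: np.ndarray
) -> np.ndarray:
    """Waterline points mapped into reconstruction coordinates."""
    enu_to_rec = gauge_transform(model, gt).inverse()
    return enu_to_rec.apply(np.asarray(waterline_enu, dtype=float))
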