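"""Ground-truth validation utilities for the synthetic benchmark.

Matches segmented label maps against the true ellipse rasterization
(one-to-one, IoU-based) and summarizes detection recall and area accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .synth import GroundTruth, rasterize_ellipses

__all__ = ["MatchResult", "match_label_maps", "true_label_map", "segmentation_score"]


@dataclass
class MatchResult:
    """One-to-one matching between true and segmented nuclei in one frame."""

    pairs: np.ndarray        # (M, 2): true label, segmented label
    ious: np.ndarray         # (M,)
    n_true: int
    n_seg: int

    @property
    def recall(self) -> float:
        return len(self.pairs) / self.n_true if self.n_true else np.nan


def match_label_maps(true_map: np.ndarray, seg_map: np.ndarray,
                     iou_threshold: float = 0.5) -> MatchResult:
    """Optimal one-to-one matching of two label maps by IoU.

    Builds the full contingency table of label overlaps in one pass and
    solves the assignment maximizing total IoU, keeping pairs above the
    threshold.
    """
    t = np.asarray(true_map).ravel()
    s = np.asarray(seg_map).ravel()
    nt, ns = int(t.max()), int(s.max())
    if nt == 0 or ns == 0:
        return MatchResult(np.empty((0, 2), int), np.empty(0), nt, ns)
    pair = t.astype(np.int64) * (ns + 1) + s
    counts = np.bincount(pair, minlength=(nt + 1) * (ns + 1)).reshape(nt + 1, ns + 1)
    inter = counts[1:, 1:].astype(float)
    area_t = counts[1:, :].sum(axis=1, keepdims=True)
    area_s = counts[:, 1:].sum(axis=0, keepdims=True)
    union = area_t + area_s - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    ti, si = linear_sum_assignment(-iou)
    keep = iou[ti, si] >= iou_threshold
    pairs = np.stack([ti[keep] + 1, si[keep] + 1], axis=1)
    return MatchResult(pairs, iou[ti, si][keep], nt, ns)


def true_label_map(gt: GroundTruth, frame: int, jittered: bool = False) -> np.ndarray:
    """Rasterize the ground-truth ellipses of one frame to a label map."""
    sub = gt.frame(frame)
    px = gt.config.pixel_size_um
    centers = sub[["x_um", "y_um"]].to_numpy() / px
    if jittered:
        centers = centers + gt.jitter_px[frame]
    return rasterize_ellipses(gt.config.frame_shape, centers,
                              sub["a_um"].to_numpy() / px,
                              sub["b_um"].to_numpy() / px,
                              sub["theta"].to_numpy())


def segmentation_score(
    gt: GroundTruth,
    label_stack: np.ndarray,
    obs: pd.DataFrame,
    frames: list[int] | None = None,
    iou_threshold: float = 0.5,
    jittered: bool = False,
) -> pd.DataFrame:
    """Recall and area error of a segmentation against ground truth.

    Returns one row per evaluated frame with columns ``frame``, ``recall``,
    ``median_area_err`` (relative, on matched pairs), ``n_true``, ``n_seg``.
    """
    if frames is None:
        frames = sorted(obs["frame"].unique())
    rows = []
    for f in frames:
        tm = true_label_map(gt, f, jittered=jittered)
        m = match_label_maps(tm, label_stack[f], iou_threshold)
        sub_gt = gt.frame(f).set_index("label")
        sub_obs = obs[obs["frame"] == f].set_index("label")
        errs = []
        for tl, sl in m.pairs:
            if sl in sub_obs.index and tl in sub_gt.index:
                a_true = sub_gt.loc[tl, "area_um2"]
                a_meas = sub_obs.loc[sl, "area_um2"]
                errs.append(abs(a_meas - a_true) / a_true)
        rows.append({
            "frame": f,
            "recall": m.recall,
            "median_area_err": float(np.median(errs)) if errs else np.nan,
            "n_true": m.n_true,
            "n_seg": m.n_seg,
        })
    return pd.DataFrame(rows)
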