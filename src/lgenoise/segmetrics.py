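"""Segmentation evaluation: Dice, precision, recall and HD95.

Overlap metrics come from pixel-wise true-positive / false-positive /
false-negative counts; the boundary metric is the 95th-percentile Hausdorff
distance (HD95) in millimetres: boundaries are foreground pixels with at
least one background neighbour under 8-connectivity, directed distances are
Euclidean (via exact distance transforms) scaled by the pixel spacing, the
95th percentile uses the linear-interpolation convention, and HD95 is the
larger of the two directed percentiles.

Zero-denominator conventions (flagged rather than silently averaged): both
masks empty -> dice 1, hd95 0; prediction empty with nonempty truth -> dice 0,
recall 0, precision undefined, hd95 undefined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "SegScores",
    "confusion_counts",
    "overlap_scores",
    "boundary_pixels",
    "hd95",
    "per_patient_scores",
]


@dataclass(frozen=True)
class SegScores:
    """Per-class overlap and boundary scores for one evaluation unit."""

    dice: float
    precision: float
    recall: float
    hd95: float
    class_id: int
    dice_defined: bool = True
    precision_defined: bool = True
    recall_defined: bool = True
    hd95_defined: bool = True


def confusion_counts(pred_mask: np.ndarray, gt_mask: np.ndarray, class_id: int) -> tuple[int, int, int]:
    """(TP, FP, FN) pixel counts for the binary indicator of ``class_id``."""
    pred_mask = np.asarray(pred_mask)
    gt_mask = np.asarray(gt_mask)
    if pred_mask.shape != gt_mask.shape:
        raise ValueError("prediction and ground truth must share a shape")
    p = pred_mask == class_id
    g = gt_mask == class_id
    tp = int((p & g).sum())
    fp = int((p & ~g).sum())
    fn = int((~p & g).sum())
    return tp, fp, fn


def overlap_scores(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """(dice, precision, recall) from counts.

    Dice = 2TP/(2TP+FP+FN); precision = TP/(TP+FP); recall = TP/(TP+FN).
    With all counts zero every metric is 1 (both masks empty); an undefined
    ratio with a zero denominator but nonzero counts elsewhere returns nan.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be nonnegative")
    if tp == 0 and fp == 0 and fn == 0:
        return 1.0, 1.0, 1.0
    dice = 2 * tp / (2 * tp + fp + fn)
    precision = tp / (tp + fp) if (tp + fp) > 0 else np.nan
    recall = tp / (tp + fn) if (tp + fn) > 0 else np.nan
    return float(dice), float(precision), float(recall)


def boundary_pixels(binary: np.ndarray) -> np.ndarray:
    """Foreground pixels with >= 1 background 8-neighbour (frame counts as background)."""
    binary = np.asarray(binary, dtype=bool)
    padded = np.pad(binary, 1, constant_values=False)
    eroded = ndimage.binary_erosion(padded, structure=np.ones((3, 3)))[1:-1, 1:-1]
    return binary & ~eroded


def _percentile95(values: np.ndarray) -> float:
    return float(np.percentile(values, 95, method="linear"))


def hd95(
    pred_mask: np.ndarray,
    gt_mask: np.ndarray,
    spacing_mm: float = 1.77,
    class_id: int | None = None,
) -> tuple[float, bool]:
    """95th-percentile Hausdorff distance in mm; returns (value, defined).

    With ``class_id`` the masks are binarised first; otherwise any nonzero
    pixel is foreground. Directed distances use the exact Euclidean distance
    transform of each boundary set, evaluated at the other boundary's pixels.
    """
    pred_mask = np.asarray(pred_mask)
    gt_mask = np.asarray(gt_mask)
    if pred_mask.shape != gt_mask.shape:
        raise ValueError("prediction and ground truth must share a shape")
    if class_id is not None:
        pred_mask = pred_mask == class_id
        gt_mask = gt_mask == class_id
    p = np.asarray(pred_mask, dtype=bool)
    g = np.asarray(gt_mask, dtype=bool)
    if not p.any() and not g.any():
        return 0.0, True
    if p.any() != g.any():
        return np.nan, False
    bp = boundary_pixels(p)
    bg = boundary_pixels(g)
    # distance_transform_edt of the complement gives distance to the nearest
    # boundary pixel at every location
    dist_to_g = ndimage.distance_transform_edt(~bg, sampling=spacing_mm)
    dist_to_p = ndimage.distance_transform_edt(~bp, sampling=spacing_mm)
    d_pg = _percentile95(dist_to_g[bp])
    d_gp = _percentile95(dist_to_p[bg])
    return float(max(d_pg, d_gp)), True


def per_patient_scores(
    slice_predictions: Sequence[np.ndarray],
    slice_ground_truths: Sequence[np.ndarray],
    class_id: int,
    spacing_mm: float = 1.77,
) -> SegScores:
    """Patient-level scores: overlap metrics from counts pooled over slices,
    HD95 as the mean of per-slice HD95 over slices where it is defined."""
    if len(slice_predictions) != len(slice_ground_truths):
        raise ValueError("prediction and ground-truth slice lists must align")
    if not slice_predictions:
        raise ValueError("patient has no slices")
    tp = fp = fn = 0
    hd_values = []
    for p, g in zip(slice_predictions, slice_ground_truths):
        a, b, c = confusion_counts(p, g, class_id)
        tp, fp, fn = tp + a, fp + b, fn + c
        val, ok = hd95(p, g, spacing_mm, class_id=class_id)
        if ok:
            hd_values.append(val)
    dice, precision, recall = overlap_scores(tp, fp, fn)
    hd_mean = float(np.mean(hd_values)) if hd_values else np.nan
    return SegScores(
        dice=dice,
        precision=precision,
        recall=recall,
        hd95=hd_mean,
        class_id=class_id,
        precision_defined=not np.isnan(precision),
        recall_defined=not np.isnan(recall),
        hd95_defined=bool(hd_values),
    )
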