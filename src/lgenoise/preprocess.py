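"""Per-slice preprocessing: intensity normalisation, one-hot masks, ROI crops.

Mirrors the data pipeline used to prepare short-axis LGE-CMR slices for
mask-conditioned synthesis: min-max scaling to [0, 1], linear rescaling to the
[-1, 1] diffusion scale, one-hot encoding of the three-class mask, and a
deterministic myocardium-centred square crop.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .phantom import SlicePair

__all__ = [
    "normalize_to_unit",
    "to_diffusion_scale",
    "to_unit_scale",
    "one_hot",
    "crop_roi",
    "load_slice_pairs",
    "select_relevant",
]

logger = logging.getLogger(__name__)


class DegenerateInputError(ValueError):
    """Raised for inputs the pipeline cannot meaningfully normalise."""


def normalize_to_unit(raw_image: np.ndarray) -> np.ndarray:
    """Min-max scale to [0, 1]; constant images are rejected.

    A constant slice carries no usable intensity range and would silently
    map to zeros, poisoning downstream noise-std estimates.
    """
    raw_image = np.asarray(raw_image, dtype=float)
    lo, hi = raw_image.min(), raw_image.max()
    if hi <= lo:
        raise DegenerateInputError("constant image cannot be min-max normalised")
    return (raw_image - lo) / (hi - lo)


def to_diffusion_scale(image01: np.ndarray) -> np.ndarray:
    """Affine map [0, 1] -> [-1, 1] (x -> 2x - 1)."""
    image01 = np.asarray(image01, dtype=float)
    if image01.min() < 0 or image01.max() > 1:
        raise ValueError("input must lie in [0, 1]")
    return 2.0 * image01 - 1.0


def to_unit_scale(image_pm1: np.ndarray) -> np.ndarray:
    """Exact inverse of :func:`to_diffusion_scale`."""
    image_pm1 = np.asarray(image_pm1, dtype=float)
    if image_pm1.min() < -1 or image_pm1.max() > 1:
        raise ValueError("input must lie in [-1, 1]")
    return (image_pm1 + 1.0) / 2.0


def one_hot(mask: np.ndarray, n_classes: int = 3) -> np.ndarray:
    """Channel-first one-hot encoding, channel order (bg, myo, scar)."""
    mask = np.asarray(mask)
    labels = np.unique(mask)
    if not np.isin(labels, np.arange(n_classes)).all():
        raise ValueError(f"unexpected labels {labels}; expected subset of 0..{n_classes - 1}")
    return (np.arange(n_classes)[:, None, None] == mask[None]).astype(np.float64)


def crop_roi(image: np.ndarray, mask: np.ndarray, size: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic size x size crop centred on the myocardial centroid.

    The centre is the integer-rounded (floor(x + 0.5), per axis) centroid of
    labels {1, 2}; the window is clamped to stay inside the frame and uses
    half-open [start, start + size) bounds.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError("image and mask must share a shape")
    h, w = mask.shape
    if size > h or size > w:
        raise ValueError("crop size exceeds image extent")
    ys, xs = np.nonzero(mask > 0)
    if ys.size == 0:
        raise ValueError("empty myocardium: cannot centre the ROI crop")
    cy = int(np.floor(ys.mean() + 0.5))
    cx = int(np.floor(xs.mean() + 0.5))
    r0 = min(max(cy - size // 2, 0), h - size)
    c0 = min(max(cx - size // 2, 0), w - size)
    sl = (slice(r0, r0 + size), slice(c0, c0 + size))
    return image[sl].copy(), mask[sl].copy()


def select_relevant(pairs: list[SlicePair]) -> list[SlicePair]:
    """Keep slices with nonempty myocardium; log how many were skipped."""
    kept = [p for p in pairs if (p.mask > 0).any()]
    skipped = len(pairs) - len(kept)
    if skipped:
        logger.info("skipped %d slices with empty myocardium", skipped)
    return kept


def load_slice_pairs(nifti_image_path: str | Path, nifti_label_path: str | Path) -> list[SlicePair]:
    """Read a (image, label) NIfTI volume pair into per-slice SlicePairs.

    The patient id is the filename stem (with a trailing ``_image`` removed)
    and the in-plane pixel spacing is taken from the header zooms.
    """
    import nibabel as nib

    img_nii = nib.load(str(nifti_image_path))
    lab_nii = nib.load(str(nifti_label_path))
    img = np.asanyarray(img_nii.dataobj).astype(float)
    lab = np.asanyarray(lab_nii.dataobj).astype(np.int64)
    if img.shape != lab.shape:
        raise ValueError(f"shape mismatch: image {img.shape} vs label {lab.shape}")
    stem = Path(nifti_image_path).name
    for suffix in (".nii.gz", ".nii"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    if stem.endswith("_image"):
        stem = stem[: -len("_image")]
    spacing = float(img_nii.header.get_zooms()[0])
    if img.ndim == 2:
        img = img[..., None]
        lab = lab[..., None]
    return [
        SlicePair(img[:, :, k], lab[:, :, k], stem, k, spacing)
        for k in range(img.shape[2])
    ]
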