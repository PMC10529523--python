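"""Binary-mask arithmetic: areas in mm², multi-annotator consensus, overlap.

The consensus operation follows the area-averaging protocol used when
several physicians each outline the same nodule: the per-annotator mask
areas are averaged and the mean area is converted back into a single
binary mask supported on the regions the annotators agree on most.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "AnnotatorMaskSet",
    "mask_area_mm2",
    "average_ground_truth",
    "overlap_metrics",
]


@dataclasses.dataclass
class AnnotatorMaskSet:
    """Two or more same-shape binary masks of one nodule."""

    masks: Sequence[np.ndarray]
    pixel_spacing_mm: float

    def __post_init__(self) -> None:
        if len(self.masks) < 2:
            raise ValueError("need at least 2 annotator masks")
        shapes = {m.shape for m in self.masks}
        if len(shapes) != 1:
            raise ValueError(f"masks have mismatched shapes: {shapes}")
        if any(not m.any() for m in self.masks):
            raise ValueError("each annotator mask must be non-empty")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")
        self.masks = [np.asarray(m, dtype=bool) for m in self.masks]


def mask_area_mm2(mask: np.ndarray, pixel_spacing_mm: float) -> float:
    """Area of the set pixels in mm² (count × spacing²)."""
    if pixel_spacing_mm <= 0:
        raise ValueError("pixel_spacing_mm must be positive")
    return float(np.count_nonzero(mask) * pixel_spacing_mm**2)


def average_ground_truth(mask_set: AnnotatorMaskSet) -> np.ndarray:
    """Consensus mask whose area is the mean of the annotators' areas.

    The pixelwise mean of the masks ranks pixels by agreement; pixels are
    admitted in decreasing mean order until the rounded mean pixel count is
    reached. Ties within one agreement level are broken by the distance
    transform of the annotators' union (interior first), so the target area
    is met to within one pixel while the result stays a superlevel set of
    the mean up to that tie-break. Raises if the annotators share no pixel
    at all (no meaningful consensus region).
    """
    masks = mask_set.masks
    stack = np.stack([m.astype(float) for m in masks])
    mean_map = stack.mean(axis=0)
    intersection = np.logical_and.reduce([m for m in masks])
    if not intersection.any():
        raise ValueError("annotator masks are disjoint; no consensus region exists")

    target_px = int(round(np.mean([int(m.sum()) for m in masks])))
    union = mean_map > 0
    # secondary score: normalized distance-to-background, strictly < one
    # agreement quantum so it only resolves ties within a mean level
    dist = ndimage.distance_transform_edt(union)
    if dist.max() > 0:
        dist = dist / (dist.max() * (len(masks) + 1.0))
    score = (mean_map + dist).ravel()
    order = np.argsort(-score, kind="stable")
    chosen = order[:target_px]
    out = np.zeros(mean_map.size, dtype=bool)
    out[chosen] = True
    return out.reshape(mean_map.shape)


def overlap_metrics(a: np.ndarray, b: np.ndarray) -> dict[str, float]:
    """Dice and Jaccard overlap of two same-shape binary masks.

    Two empty masks are defined to agree perfectly (both metrics 1.0).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    ni = int((a & b).sum())
    if na == 0 and nb == 0:
        return {"dice": 1.0, "jaccard": 1.0}
    dice = 2.0 * ni / (na + nb)
    jaccard = ni / (na + nb - ni)
    return {"dice": float(dice), "jaccard": float(jaccard)}
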