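"""Segmentation of the three base areas A_T, A_R, A_B.

The total specimen area A_T comes from the ROI; the mobile-cell area A_R
and the fixed-structure area A_B come from a relative RGB-plane threshold
followed by morphological cleanup.

Morphology convention: square structuring elements; pixels outside the
frame are treated as false for both dilation and erosion (matching
``scipy.ndimage`` with ``border_value=0``), which is also the convention of
the brute-force oracles in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, ValidationError
from .image_io import ColorImage, RoiSpec, mask_area, rasterize_roi

__all__ = [
    "SegmentationParams",
    "segment_total",
    "segment_relative_color",
    "clean_red_mask",
    "clean_blue_mask",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable constants of the segmentation stage.

    ``ratio_threshold`` 1.6 encodes "at least 60% higher"; the small-object
    cutoff for the structure channel is a fraction of the specimen area A_T.
    """

    ratio_threshold: float = 1.6
    red_cleanup_kernel_px: int = 3
    blue_min_object_fraction: float = 0.0001
    blue_closing_kernel_px: int = 11
    component_connectivity: int = 8

    def __post_init__(self) -> None:
        if not self.ratio_threshold > 1:
            raise ValidationError("ratio_threshold must exceed 1")
        for name in ("red_cleanup_kernel_px", "blue_closing_kernel_px"):
            k = getattr(self, name)
            if k < 1 or k % 2 == 0:
                raise ValidationError(f"{name} must be an odd positive integer")
        if not 0 < self.blue_min_object_fraction < 1:
            raise ValidationError("blue_min_object_fraction must be in (0, 1)")
        if self.component_connectivity not in (4, 8):
            raise ValidationError("component_connectivity must be 4 or 8")


def _square(k: int) -> np.ndarray:
    return np.ones((k, k), dtype=bool)


def segment_total(image: ColorImage, roi: RoiSpec) -> np.ndarray:
    """Rasterize the ROI into the total specimen mask A_T."""
    return rasterize_roi(roi, image.shape)


def segment_relative_color(
    image: ColorImage,
    target_channel: str,
    params: SegmentationParams,
    a_t: np.ndarray,
) -> np.ndarray:
    """Relative RGB-plane thresholding inside the specimen mask.

    For ``target_channel='red'`` a pixel is selected iff its red value is at
    least ``ratio_threshold`` times both the green and the blue value (the
    comparison is inclusive); for ``'blue'`` the roles of red and blue swap.
    """
    if a_t.shape != image.shape:
        raise ValidationError(
            f"A_T shape {a_t.shape} does not match image shape {image.shape}"
        )
    px = image.pixels.astype(np.float64)
    r, g, b = px[:, :, 0], px[:, :, 1], px[:, :, 2]
    t = params.ratio_threshold
    if target_channel == "red":
        hit = (r >= t * g) & (r >= t * b)
    elif target_channel == "blue":
        hit = (b >= t * g) & (b >= t * r)
    else:
        raise ValidationError(f"target_channel must be 'red' or 'blue', got {target_channel!r}")
    return hit & np.asarray(a_t, dtype=bool)


def clean_red_mask(
    mask: np.ndarray,
    params: SegmentationParams,
    a_t: np.ndarray | None = None,
) -> np.ndarray:
    """Morphological closing then opening of the raw cell mask -> A_R.

    Removes single-pixel noise and granular texture; the result is
    re-intersected with A_T so closing cannot leak outside the specimen.
    """
    k = params.red_cleanup_kernel_px
    se = _square(k)
    out = ndimage.binary_opening(ndimage.binary_closing(mask, structure=se), structure=se)
    if a_t is not None:
        out &= np.asarray(a_t, dtype=bool)
    return out


def clean_blue_mask(
    mask: np.ndarray,
    params: SegmentationParams,
    a_t: np.ndarray,
) -> np.ndarray:
    """Small-object scrapping then closing of the raw structure mask -> A_B.

    Connected components (8-connectivity by default) smaller than
    ``blue_min_object_fraction * |A_T|`` pixels are deleted, then a closing
    with an 11x11 square element smooths the remainder; the result is
    re-intersected with A_T.
    """
    a_t = np.asarray(a_t, dtype=bool)
    area_t = mask_area(a_t)
    if area_t == 0:
        raise DegenerateInputError("specimen area A_T is empty")
    structure = ndimage.generate_binary_structure(2, 2 if params.component_connectivity == 8 else 1)
    labels, n = ndimage.label(mask, structure=structure)
    if n:
        cutoff = params.blue_min_object_fraction * area_t
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= cutoff) + 1
        mask = np.isin(labels, keep)
    else:
        mask = np.zeros_like(a_t)
    out = ndimage.binary_closing(mask, structure=_square(params.blue_closing_kernel_px))
    return out & a_t
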