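"""Graded neighborhood construction and density fractions.

The structure mask is dilated with a growing series of square kernels; the
dilated band minus the structure is the neighborhood area A_N, the specimen
minus the dilated area is the residual area A_D, and the fractions of those
areas covered by cell pixels (F_N, F_D) are the method's core output.

Kernel series: at the reference scale of 1.5 px/µm the widths 10, 20, 30 µm
map to square kernels of side 31, 61, 91 pixels (base 31 px, step 30 px).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, UndefinedFractionError, ValidationError
from .image_io import ColorImage, RoiSpec, mask_area
from .segmentation import (
    SegmentationParams,
    clean_blue_mask,
    clean_red_mask,
    segment_relative_color,
    segment_total,
)

__all__ = [
    "NeighborhoodResult",
    "DEFAULT_WIDTHS_UM",
    "kernel_px_for_width",
    "dilate",
    "neighborhood_areas",
    "density_fractions",
    "analyze_image",
    "analyze_masks",
]

#: Default neighborhood widths in µm (10 up to 50 in steps of 10).
DEFAULT_WIDTHS_UM = (10.0, 20.0, 30.0, 40.0, 50.0)


@dataclass
class NeighborhoodResult:
    """Area bookkeeping and density fractions for one image at one width.

    ``ratio`` is F_N / F_D, NaN when F_D vanishes. ``area_R`` and
    ``area_RB`` (cell pixels lying on the structure itself, counted in
    neither fraction) are audit values.
    """

    image_id: str
    patient_id: str
    width_um: float
    kernel_px: int
    area_T: int
    area_B: int
    area_N: int
    area_D: int
    area_NR: int
    area_DR: int
    F_N: float
    F_D: float
    ratio: float
    area_R: int = 0
    area_RB: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


def kernel_px_for_width(width_um: float, scale_px_per_um: float) -> int:
    """Side length in pixels of the square dilation kernel for a width.

    ``2 * round(width_um * scale) + 1``; at 1.5 px/µm this reproduces the
    31/61/91 px series for 10/20/30 µm. Rounding is half-away-from-zero.
    """
    if not width_um > 0:
        raise ValidationError("width_um must be positive")
    if not scale_px_per_um > 0:
        raise ValidationError("scale_px_per_um must be positive")
    half = math.floor(width_um * scale_px_per_um + 0.5)
    return 2 * half + 1


def dilate(structure: np.ndarray, kernel_px: int) -> np.ndarray:
    """Binary dilation with a centered solid square element of odd side.

    Equivalent to thresholding the Chebyshev distance to the structure at
    ``(kernel_px - 1) / 2``; the frame border behaves as if padded false.
    """
    if kernel_px < 1 or kernel_px % 2 == 0:
        raise ValidationError("kernel_px must be an odd positive integer")
    structure = np.asarray(structure, dtype=bool)
    if kernel_px == 1:
        return structure.copy()
    return ndimage.binary_dilation(structure, structure=np.ones((kernel_px, kernel_px), bool))


def neighborhood_areas(
    structure_b: np.ndarray,
    a_t: np.ndarray,
    kernel_px: int,
    clip_to_specimen: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Neighborhood mask A_N and residual mask A_D for one kernel size.

    ``A_N = (dilate(A_B) ∩ A_T) \\ A_B`` and ``A_D = A_T \\ dilate(A_B)``;
    A_B, A_N and A_D partition A_T exactly. With ``clip_to_specimen`` off
    the dilated area is not intersected with A_T before the subtractions
    (A_D is unchanged; A_N may extend outside the specimen).
    """
    structure_b = np.asarray(structure_b, dtype=bool)
    a_t = np.asarray(a_t, dtype=bool)
    if structure_b.shape != a_t.shape:
        raise ValidationError("structure and specimen masks must share a shape")
    if not np.any(structure_b):
        raise DegenerateInputError("structure mask A_B is empty; neighborhoods undefined")
    dilated = dilate(structure_b, kernel_px)
    a_d = a_t & ~dilated
    if clip_to_specimen:
        dilated &= a_t
    a_n = dilated & ~structure_b
    return a_n, a_d


def density_fractions(
    a_r: np.ndarray, a_n: np.ndarray, a_d: np.ndarray
) -> tuple[float, float]:
    """Fractions of neighborhood/residual area covered by cell pixels.

    ``F_N = |A_R ∩ A_N| / |A_N|`` and ``F_D = |A_R ∩ A_D| / |A_D|``, both
    dimensionless in [0, 1].
    """
    if not (a_r.shape == a_n.shape == a_d.shape):
        raise ValidationError("masks must share one shape")
    n_area = mask_area(a_n)
    d_area = mask_area(a_d)
    if n_area == 0:
        raise UndefinedFractionError("a_n")
    if d_area == 0:
        raise UndefinedFractionError("a_d")
    f_n = mask_area(a_r & a_n) / n_area
    f_d = mask_area(a_r & a_d) / d_area
    return f_n, f_d


def analyze_masks(
    a_r: np.ndarray,
    a_b: np.ndarray,
    a_t: np.ndarray,
    widths_um,
    scale_px_per_um: float,
    image_id: str = "",
    patient_id: str = "",
    clip_to_specimen: bool = True,
) -> list[NeighborhoodResult]:
    """Neighborhood analysis on already-segmented masks, one result per width."""
    widths = [float(w) for w in widths_um]
    if any(b >= a for a, b in zip(widths[1:], widths)):
        raise ValidationError("widths_um must be strictly increasing")
    area_t = mask_area(a_t)
    if area_t == 0:
        raise DegenerateInputError("specimen area A_T is empty")
    area_b = mask_area(a_b)
    area_r = mask_area(a_r)
    area_rb = mask_area(a_r & a_b)
    results = []
    for width in widths:
        kernel = kernel_px_for_width(width, scale_px_per_um)
        a_n, a_d = neighborhood_areas(a_b, a_t, kernel, clip_to_specimen)
        f_n, f_d = density_fractions(a_r, a_n, a_d)
        area_nr = mask_area(a_r & a_n)
        area_dr = mask_area(a_r & a_d)
        results.append(
            NeighborhoodResult(
                image_id=image_id,
                patient_id=patient_id,
                width_um=width,
                kernel_px=kernel,
                area_T=area_t,
                area_B=area_b,
                area_N=mask_area(a_n),
                area_D=mask_area(a_d),
                area_NR=area_nr,
                area_DR=area_dr,
                F_N=f_n,
                F_D=f_d,
                ratio=(f_n / f_d) if f_d > 0 else float("nan"),
                area_R=area_r,
                area_RB=area_rb,
            )
        )
    return results


def analyze_image(
    image: ColorImage,
    roi: RoiSpec,
    widths_um=DEFAULT_WIDTHS_UM,
    params: SegmentationParams | None = None,
    image_id: str = "",
    patient_id: str = "",
    clip_to_specimen: bool = True,
    return_masks: bool = False,
):
    """Full single-image pipeline: segment A_T, A_R, A_B, then analyze.

    Returns a list of NeighborhoodResult (one per width); with
    ``return_masks`` also returns the dict of segmented masks.
    """
    params = params or SegmentationParams()
    a_t = segment_total(image, roi)
    if mask_area(a_t) == 0:
        raise DegenerateInputError("specimen area A_T is empty")
    raw_red = segment_relative_color(image, "red", params, a_t)
    a_r = clean_red_mask(raw_red, params, a_t)
    raw_blue = segment_relative_color(image, "blue", params, a_t)
    a_b = clean_blue_mask(raw_blue, params, a_t)
    results = analyze_masks(
        a_r,
        a_b,
        a_t,
        widths_um,
        image.scale_px_per_um,
        image_id=image_id,
        patient_id=patient_id,
        clip_to_specimen=clip_to_specimen,
    )
    if return_masks:
        return results, {"a_t": a_t, "a_r": a_r, "a_b": a_b}
    return results
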