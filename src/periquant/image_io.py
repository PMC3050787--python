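"""Raster, ROI and table I/O.

Coordinate convention (used package-wide): 0-based ``(row, col)`` with row 0
at the top of the image. Binary masks are plain ``numpy`` boolean arrays of
shape ``(H, W)``; color images are ``uint8`` arrays of shape ``(H, W, 3)``
with channels in R, G, B order.

Polygon membership uses pixel centers (integer coordinates) and the even-odd
rule; a pixel whose center lies exactly on a polygon edge counts as inside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .errors import FormatError, ValidationError

__all__ = [
    "ColorImage",
    "RoiSpec",
    "read_color_image",
    "write_color_image",
    "read_mask_png",
    "write_mask_png",
    "read_roi_json",
    "write_roi_json",
    "rasterize_roi",
    "mask_area",
    "write_results_table",
    "read_results_table",
    "RESULT_COLUMNS",
]

#: Default physical scale: 100 µm correspond to 150 pixels.
DEFAULT_SCALE_PX_PER_UM = 1.5


@dataclass
class ColorImage:
    """An 8-bit RGB raster plus its physical scale in pixels per micrometer."""

    pixels: np.ndarray
    scale_px_per_um: float = DEFAULT_SCALE_PX_PER_UM

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValidationError(
                f"ColorImage requires an HxWx3 array, got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValidationError("ColorImage must have H >= 1 and W >= 1")
        if self.pixels.dtype != np.uint8:
            raise FormatError(
                f"ColorImage requires 8 bits per channel, got dtype {self.pixels.dtype}"
            )
        if not self.scale_px_per_um > 0:
            raise ValidationError("scale_px_per_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        """(H, W) of the raster."""
        return self.pixels.shape[:2]


def _as_polygon(vertices: Sequence[Sequence[float]]) -> np.ndarray:
    poly = np.asarray(vertices, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
        raise ValidationError(
            "polygon must be a list of >= 3 (row, col) vertices, "
            f"got array of shape {poly.shape}"
        )
    return poly


@dataclass
class RoiSpec:
    """Region-of-interest: include polygons minus exclude polygons.

    Polygons are closed vertex lists in (row, col) pixel coordinates; the
    closing edge from the last vertex back to the first is implicit.
    """

    include_polygons: list = field(default_factory=list)
    exclude_polygons: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.include_polygons = [_as_polygon(p) for p in self.include_polygons]
        self.exclude_polygons = [_as_polygon(p) for p in self.exclude_polygons]

    @staticmethod
    def full_frame(shape: tuple[int, int]) -> "RoiSpec":
        """ROI covering every pixel of an (H, W) frame."""
        h, w = shape
        rect = [(-0.5, -0.5), (-0.5, w - 0.5), (h - 0.5, w - 0.5), (h - 0.5, -0.5)]
        return RoiSpec(include_polygons=[rect])


def read_color_image(path, scale_px_per_um: float = DEFAULT_SCALE_PX_PER_UM) -> ColorImage:
    """Read an 8-bit RGB TIFF or PNG.

    RGBA inputs have their alpha channel stripped; grayscale inputs and
    bit depths other than 8 per channel are rejected.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        with Image.open(path) as img:
            if img.mode == "RGBA":
                img = img.convert("RGB")
            if img.mode not in ("RGB",):
                raise FormatError(
                    f"unsupported image mode {img.mode!r}; an RGB image is required"
                )
            arr = np.asarray(img)
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(
            f"expected an RGB image, got array of shape {arr.shape} from {path}"
        )
    if arr.dtype != np.uint8:
        raise FormatError(
            f"expected 8 bits per channel, got dtype {arr.dtype} from {path}"
        )
    return ColorImage(pixels=arr.copy(), scale_px_per_um=scale_px_per_um)


def write_color_image(image: ColorImage, path) -> None:
    """Write an RGB raster as TIFF or PNG depending on the file suffix."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.pixels, photometric="rgb")
    else:
        Image.fromarray(image.pixels, mode="RGB").save(path)


def write_mask_png(mask: np.ndarray, path) -> None:
    """Persist a boolean mask as a single-channel 8-bit PNG (0/255)."""
    arr = (np.asarray(mask, dtype=bool).astype(np.uint8)) * 255
    Image.fromarray(arr, mode="L").save(path)


def read_mask_png(path) -> np.ndarray:
    """Read a 0/255 single-channel PNG back into a boolean mask."""
    with Image.open(path) as img:
        if img.mode != "L":
            img = img.convert("L")
        arr = np.asarray(img)
    return arr > 127


def write_roi_json(roi: RoiSpec, path) -> None:
    doc = {
        "include": [np.asarray(p).tolist() for p in roi.include_polygons],
        "exclude": [np.asarray(p).tolist() for p in roi.exclude_polygons],
    }
    Path(path).write_text(json.dumps(doc))


def read_roi_json(path) -> RoiSpec:
    doc = json.loads(Path(path).read_text())
    if not isinstance(doc, dict) or "include" not in doc:
        raise FormatError(f"ROI file {path} lacks an 'include' key")
    return RoiSpec(
        include_polygons=doc.get("include", []),
        exclude_polygons=doc.get("exclude", []),
    )


def _polygon_membership(rr: np.ndarray, cc: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Even-odd membership of pixel centers, edges inclusive.

    ``rr``/``cc`` are flat arrays of pixel-center coordinates; ``poly`` is an
    (N, 2) array of (row, col) vertices.
    """
    y = rr.astype(float)
    x = cc.astype(float)
    inside = np.zeros(y.shape, dtype=bool)
    on_edge = np.zeros(y.shape, dtype=bool)
    n = len(poly)
    for i in range(n):
        r1, c1 = poly[i]
        r2, c2 = poly[(i + 1) % n]
        # distance-free on-segment test: zero cross product + bounding box
        cross = (c2 - c1) * (y - r1) - (r2 - r1) * (x - c1)
        seg_len = max(abs(r2 - r1), abs(c2 - c1), 1.0)
        tol = 1e-9 * seg_len
        bbox = (
            (x >= min(c1, c2) - 1e-9)
            & (x <= max(c1, c2) + 1e-9)
            & (y >= min(r1, r2) - 1e-9)
            & (y <= max(r1, r2) + 1e-9)
        )
        on_edge |= (np.abs(cross) <= tol) & bbox
        # ray casting, half-open in y so shared vertices are counted once
        crosses = (r1 > y) != (r2 > y)
        if np.any(crosses):
            with np.errstate(divide="ignore", invalid="ignore"):
                x_int = c1 + (y - r1) * (c2 - c1) / (r2 - r1)
            inside ^= crosses & (x < x_int)
    return inside | on_edge


def rasterize_roi(roi: RoiSpec, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a RoiSpec onto an (H, W) grid.

    A pixel is true iff its center lies in some include polygon and in no
    exclude polygon (even-odd rule, edge-inclusive), clipped to the frame.
    """
    h, w = int(shape[0]), int(shape[1])
    if h < 1 or w < 1:
        raise ValidationError(f"invalid raster shape {shape}")
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    rr = rr.ravel()
    cc = cc.ravel()
    include = np.zeros(h * w, dtype=bool)
    for poly in roi.include_polygons:
        include |= _polygon_membership(rr, cc, poly)
    exclude = np.zeros(h * w, dtype=bool)
    for poly in roi.exclude_polygons:
        exclude |= _polygon_membership(rr, cc, poly)
    return (include & ~exclude).reshape(h, w)


def mask_area(mask: np.ndarray) -> int:
    """Number of true pixels in a binary mask."""
    return int(np.count_nonzero(mask))


RESULT_COLUMNS = [
    "image_id",
    "patient_id",
    "width_um",
    "kernel_px",
    "area_T",
    "area_B",
    "area_N",
    "area_D",
    "area_NR",
    "area_DR",
    "F_N",
    "F_D",
    "ratio",
    # audit columns (not part of the core contract)
    "area_R",
    "area_RB",
]


def write_results_table(results: Iterable, path) -> None:
    """Write per-(image, width) neighborhood results as CSV.

    One row per NeighborhoodResult; floats carry >= 6 significant digits.
    """
    rows = [r.as_dict() for r in results]
    if not rows:
        raise ValidationError("results must be nonempty")
    frame = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    frame.to_csv(path, index=False, float_format="%.9g")


def read_results_table(path) -> pd.DataFrame:
    """Read a results CSV back into a DataFrame."""
    return pd.read_csv(path)
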