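"""Random-cell null model.

Artificial cells are grown from uniformly placed seed points by repeatedly
adding one random allowed pixel adjacent to the current blob, mimicking the
irregular outline of real stained cells. A study runs many replicates per
seed count and summarizes the density fractions of the resulting random
patterns against a fixed neighborhood geometry, yielding the mean and SD of
the random-distribution reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InfeasibleDensityError, ValidationError
from .image_io import mask_area
from .neighborhood import kernel_px_for_width, neighborhood_areas

__all__ = [
    "SimulationConfig",
    "SimulationStudy",
    "grow_random_cell",
    "generate_random_cell_image",
    "run_simulation_study",
    "estimate_cell_area",
]

_OFFSETS_4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
_OFFSETS_8 = _OFFSETS_4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of a random-distribution study.

    Defaults follow the reference design: seed counts 100..500 in steps of
    100 with 100 replicates each, i.e. 500 generated images in total.
    """

    seed_counts: tuple = (100, 200, 300, 400, 500)
    replicates_per_count: int = 100
    target_cell_area_px: int = 40
    rng_seed: int = 0
    growth_connectivity: int = 4

    def __post_init__(self) -> None:
        if not self.seed_counts or any(int(s) < 1 for s in self.seed_counts):
            raise ValidationError("seed_counts must be positive integers")
        if self.replicates_per_count < 1:
            raise ValidationError("replicates_per_count must be positive")
        if self.target_cell_area_px < 1:
            raise ValidationError("target_cell_area_px must be positive")
        if self.growth_connectivity not in (4, 8):
            raise ValidationError("growth_connectivity must be 4 or 8")

    @property
    def n_images(self) -> int:
        return len(self.seed_counts) * self.replicates_per_count


@dataclass
class SimulationStudy:
    """Per-replicate fractions and per-(seed count, width) summary tables."""

    config: SimulationConfig
    per_replicate: pd.DataFrame = field(default_factory=pd.DataFrame)
    summary: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_images(self) -> int:
        """Number of distinct random-cell images recorded in the study."""
        if self.per_replicate.empty:
            return 0
        return len(
            self.per_replicate[["seed_count", "replicate_index"]].drop_duplicates()
        )


def grow_random_cell(
    seed: tuple[int, int],
    target_area_px: int,
    allowed: np.ndarray,
    rng: np.random.Generator,
    connectivity: int = 4,
) -> np.ndarray:
    """Grow one connected blob from a seed pixel by random accretion.

    Each step adds one pixel chosen uniformly among the unoccupied allowed
    pixels adjacent to the current blob; growth stops at ``target_area_px``
    pixels or when the reachable allowed region is exhausted.
    """
    allowed = np.asarray(allowed, dtype=bool)
    h, w = allowed.shape
    r0, c0 = int(seed[0]), int(seed[1])
    if not (0 <= r0 < h and 0 <= c0 < w) or not allowed[r0, c0]:
        raise ValidationError(f"seed {seed} lies outside the allowed region")
    if target_area_px < 1:
        raise ValidationError("target_area_px must be >= 1")
    offsets = _OFFSETS_4 if connectivity == 4 else _OFFSETS_8
    blob = {(r0, c0)}
    candidates: list[tuple[int, int]] = []
    in_candidates: set[tuple[int, int]] = set()

    def push_neighbors(r: int, c: int) -> None:
        for dr, dc in offsets:
            nr, nc = r + dr, c + dc
            if 0 <= nr < h and 0 <= nc < w and allowed[nr, nc]:
                p = (nr, nc)
                if p not in blob and p not in in_candidates:
                    candidates.append(p)
                    in_candidates.add(p)

    push_neighbors(r0, c0)
    while len(blob) < target_area_px and candidates:
        i = int(rng.integers(len(candidates)))
        p = candidates[i]
        candidates[i] = candidates[-1]
        candidates.pop()
        in_candidates.discard(p)
        blob.add(p)
        push_neighbors(*p)

    out = np.zeros((h, w), dtype=bool)
    rows, cols = zip(*blob)
    out[list(rows), list(cols)] = True
    return out


def generate_random_cell_image(
    a_t: np.ndarray,
    forbidden: np.ndarray | None,
    n_seeds: int,
    target_area: int,
    rng: np.random.Generator,
    connectivity: int = 4,
) -> np.ndarray:
    """Union mask of ``n_seeds`` random cells confined to ``a_t \\ forbidden``.

    Seed points are drawn uniformly without replacement; grown cells may
    overlap and merge, as real stained areas do.
    """
    a_t = np.asarray(a_t, dtype=bool)
    allowed = a_t if forbidden is None else (a_t & ~np.asarray(forbidden, dtype=bool))
    out = np.zeros_like(allowed)
    if n_seeds == 0:
        return out
    flat = np.flatnonzero(allowed)
    if len(flat) < n_seeds:
        raise InfeasibleDensityError(
            f"{n_seeds} seeds requested but only {len(flat)} allowed pixels"
        )
    seeds = rng.choice(flat, size=n_seeds, replace=False)
    w = allowed.shape[1]
    for s in seeds:
        out |= grow_random_cell(
            (int(s) // w, int(s) % w), target_area, allowed, rng, connectivity
        )
    return out


def estimate_cell_area(a_r: np.ndarray, connectivity: int = 8) -> int:
    """Median connected-component area of a real cell mask, in pixels.

    Helper for choosing ``target_cell_area_px`` so artificial cells match
    the size of real ones.
    """
    structure = ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)
    labels, n = ndimage.label(np.asarray(a_r, dtype=bool), structure=structure)
    if n == 0:
        raise ValidationError("cell mask has no components to estimate a size from")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return max(1, int(round(float(np.median(sizes)))))


def run_simulation_study(
    a_t: np.ndarray,
    structure_b: np.ndarray,
    widths_um,
    config: SimulationConfig,
    scale_px_per_um: float,
    clip_to_specimen: bool = True,
) -> SimulationStudy:
    """Run the full random-distribution study against one geometry.

    For every (seed count, replicate) one random-cell image is generated and
    its density fractions are computed at every width; replicate RNG streams
    are derived deterministically from ``config.rng_seed`` so any single
    replicate is reproducible in isolation via
    ``np.random.default_rng([rng_seed, seed_count, replicate_index])``.
    """
    a_t = np.asarray(a_t, dtype=bool)
    structure_b = np.asarray(structure_b, dtype=bool)
    widths = [float(w) for w in widths_um]
    geometry = {}
    for width in widths:
        kernel = kernel_px_for_width(width, scale_px_per_um)
        a_n, a_d = neighborhood_areas(structure_b, a_t, kernel, clip_to_specimen)
        geometry[width] = (a_n, mask_area(a_n), a_d, mask_area(a_d))

    rows = []
    for seed_count in config.seed_counts:
        for rep in range(config.replicates_per_count):
            rng = np.random.default_rng([config.rng_seed, int(seed_count), rep])
            mask = generate_random_cell_image(
                a_t,
                structure_b,
                int(seed_count),
                config.target_cell_area_px,
                rng,
                config.growth_connectivity,
            )
            for width in widths:
                a_n, n_area, a_d, d_area = geometry[width]
                if n_area == 0 or d_area == 0:
                    raise ValidationError(
                        f"degenerate geometry at width {width}: empty area"
                    )
                f_n = mask_area(mask & a_n) / n_area
                f_d = mask_area(mask & a_d) / d_area
                rows.append(
                    {
                        "seed_count": int(seed_count),
                        "replicate_index": rep,
                        "width_um": width,
                        "F_N": f_n,
                        "F_D": f_d,
                        "ratio": (f_n / f_d) if f_d > 0 else np.nan,
                    }
                )
    per_replicate = pd.DataFrame(rows)
    grouped = per_replicate.groupby(["seed_count", "width_um"])
    summary = grouped.agg(
        mean_F_N=("F_N", "mean"),
        sd_F_N=("F_N", "std"),
        mean_F_D=("F_D", "mean"),
        sd_F_D=("F_D", "std"),
        mean_ratio=("ratio", "mean"),
        sd_ratio=("ratio", "std"),
        n_replicates=("ratio", "size"),
    ).reset_index()
    return SimulationStudy(config=config, per_replicate=per_replicate, summary=summary)
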