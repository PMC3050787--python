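"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the code paths they check: morphology
is re-derived from set algebra over explicit pixel sets, polygon membership
from shapely, and the signed-rank null from exhaustive sign enumeration.
"""

import itertools

import numpy as np
import pytest

from periquant import FixtureSpec, make_fixture


# ---------------------------------------------------------------- morphology


def oracle_dilate(mask: np.ndarray, kernel_px: int) -> np.ndarray:
    """Chebyshev-distance-threshold construction of square dilation."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    half = (kernel_px - 1) // 2
    rs, cs = np.nonzero(mask)
    out = np.zeros_like(mask)
    if len(rs) == 0:
        return out
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    cheb = np.maximum(
        np.abs(rr[:, :, None] - rs[None, None, :]),
        np.abs(cc[:, :, None] - cs[None, None, :]),
    ).min(axis=2)
    return cheb <= half


def oracle_erode(mask: np.ndarray, kernel_px: int) -> np.ndarray:
    """Set-algebra erosion; pixels outside the frame count as false."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    half = (kernel_px - 1) // 2
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            ok = True
            for dr in range(-half, half + 1):
                for dc in range(-half, half + 1):
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < h and 0 <= cc < w and mask[rr, cc]):
                        ok = False
                        break
                if not ok:
                    break
            out[r, c] = ok
    return out


def oracle_close(mask, kernel_px):
    return oracle_erode(oracle_dilate(mask, kernel_px), kernel_px)


def oracle_open(mask, kernel_px):
    return oracle_dilate(oracle_erode(mask, kernel_px), kernel_px)


# ------------------------------------------------------------------ wilcoxon


def oracle_signed_rank_p(diffs) -> float:
    """Two-tailed signed-rank p by exhaustive sign-flip enumeration (n<=16)."""
    from scipy.stats import rankdata

    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    ws = np.asarray(ws)
    tol = 1e-9
    p_le = np.mean(ws <= w_obs + tol)
    p_ge = np.mean(ws >= w_obs - tol)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


# ------------------------------------------------------------------ fixtures


SMALL_RING = dict(
    frame=(96, 96),
    structure_params={"radius_px": 16, "thickness_px": 3},
    n_cells=50,
    cell_area_px=9,
)


@pytest.fixture(scope="session")
def ring_fixture():
    """A 96x96 ring-structure micrograph with uniform cells, noise-free."""
    spec = FixtureSpec(rng_seed=11, **SMALL_RING)
    return make_fixture(spec)


@pytest.fixture(scope="session")
def ring_geometry():
    """Cell-free (a_t, a_b) masks of a 160x160 ring, for simulation runs."""
    spec = FixtureSpec(
        frame=(160, 160),
        structure_params={"radius_px": 22, "thickness_px": 3},
        n_cells=0,
        rng_seed=1,
    )
    _, _, truth = make_fixture(spec)
    return truth["a_t"], truth["a_b"]


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
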