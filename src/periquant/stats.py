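"""Patient-level summarization and paired nonparametric testing.

Each patient contributes one robust observation per width: the median of
the density fractions over that patient's samples. The paired Wilcoxon
signed-rank test compares median F_N against median F_D across patients;
zero differences are dropped before ranking, ties share average ranks, and
the exact null distribution is used for n <= 25 (normal approximation with
tie correction above that).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .errors import ValidationError
from .neighborhood import NeighborhoodResult
from .simulation import SimulationStudy

__all__ = [
    "PatientSummary",
    "TestResult",
    "summarize_patients",
    "paired_wilcoxon",
    "wilcoxon_signed_rank",
    "wilcoxon_by_width",
    "qq_plot_data",
]

EXACT_N_MAX = 25


@dataclass
class PatientSummary:
    patient_id: str
    width_um: float
    median_F_N: float
    median_F_D: float
    n_samples: int
    normalized_ratio: float


@dataclass
class TestResult:
    width_um: float
    n_patients: int
    statistic: float
    p_two_tailed: float
    significant: bool
    method: str
    underpowered: bool = False


def _mapping_to_dict(mapping) -> dict:
    if isinstance(mapping, dict):
        return {str(k): str(v) for k, v in mapping.items()}
    frame = pd.DataFrame(mapping)
    if not {"image_id", "patient_id"} <= set(frame.columns):
        raise ValidationError(
            "mapping table must have 'image_id' and 'patient_id' columns"
        )
    return {str(r.image_id): str(r.patient_id) for r in frame.itertuples()}


def summarize_patients(
    results: list[NeighborhoodResult], mapping
) -> list[PatientSummary]:
    """One PatientSummary per (patient, width): medians over the samples.

    ``mapping`` is a sample-to-patient table (DataFrame/records with
    ``image_id``/``patient_id`` columns, or a plain dict). Every image_id in
    ``results`` must be mapped.
    """
    lookup = _mapping_to_dict(mapping)
    rows = []
    for res in results:
        if str(res.image_id) not in lookup:
            raise ValidationError(f"image {res.image_id!r} missing from mapping")
        rows.append(
            {
                "patient_id": lookup[str(res.image_id)],
                "width_um": float(res.width_um),
                "F_N": res.F_N,
                "F_D": res.F_D,
            }
        )
    frame = pd.DataFrame(rows)
    out = []
    for (patient, width), grp in frame.groupby(["patient_id", "width_um"], sort=True):
        med_n = float(grp["F_N"].median())
        med_d = float(grp["F_D"].median())
        out.append(
            PatientSummary(
                patient_id=patient,
                width_um=width,
                median_F_N=med_n,
                median_F_D=med_d,
                n_samples=len(grp),
                normalized_ratio=(med_n / med_d) if med_d > 0 else float("nan"),
            )
        )
    return out


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-tailed p for the signed-rank statistic.

    ``p = 2 * min(P(W <= w), P(W >= w))`` under uniform random signs,
    capped at 1. Mid-ranks are handled by doubling so all sums are integer;
    the null distribution is built by dynamic-programming convolution.
    """
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    w2 = int(np.rint(2 * w_plus))
    denom = 2.0 ** len(ranks)
    p_le = counts[: w2 + 1].sum() / denom
    p_ge = counts[w2:].sum() / denom
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(x, y) -> tuple[float, float, str]:
    """Paired Wilcoxon signed-rank test; returns (W+, two-tailed p, method).

    Zero differences are dropped; absolute differences receive average
    ranks. Exact distribution for n <= 25 remaining pairs, otherwise a
    tie-corrected normal approximation without continuity correction.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0, "degenerate"
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_N_MAX:
        return w_plus, _exact_signed_rank_p(ranks, w_plus), "exact"
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= np.sum(tie_counts**3 - tie_counts) / 48.0
    if var <= 0:
        return w_plus, 1.0, "degenerate"
    z = (w_plus - mu) / np.sqrt(var)
    return w_plus, float(min(1.0, 2.0 * norm.sf(abs(z)))), "normal"


def paired_wilcoxon(
    summaries: list[PatientSummary], width: float, alpha: float = 0.01
) -> TestResult:
    """Signed-rank test of median F_N vs median F_D at one width."""
    at_width = [s for s in summaries if s.width_um == float(width)]
    if not at_width:
        raise ValidationError(f"no patient summaries at width {width}")
    x = [s.median_F_N for s in at_width]
    y = [s.median_F_D for s in at_width]
    stat, p, method = wilcoxon_signed_rank(x, y)
    return TestResult(
        width_um=float(width),
        n_patients=len(at_width),
        statistic=stat,
        p_two_tailed=p,
        significant=bool(p < alpha),
        method=method,
        underpowered=len(at_width) < 6,
    )


def wilcoxon_by_width(
    summaries: list[PatientSummary],
    widths,
    alpha: float = 0.01,
    holm: bool = False,
) -> list[TestResult]:
    """Per-width tests; optional Holm step-down correction across widths."""
    results = [paired_wilcoxon(summaries, w, alpha) for w in widths]
    if holm:
        order = np.argsort([r.p_two_tailed for r in results])
        m = len(results)
        running_max = 0.0
        for rank, idx in enumerate(order):
            adj = min(1.0, (m - rank) * results[idx].p_two_tailed)
            running_max = max(running_max, adj)
            results[idx].p_two_tailed = running_max
            results[idx].significant = bool(running_max < alpha)
    return results


def qq_plot_data(
    summaries: list[PatientSummary], null: SimulationStudy, width: float
) -> dict[str, pd.DataFrame]:
    """Data behind the observed-vs-random density plot at one width.

    ``patients``: one (median_F_N, median_F_D) dot per patient.
    ``null_line``: per-seed-count simulated means and SDs of both fractions.
    ``pooled``: the random-distribution reference pooled over seed counts.
    """
    width = float(width)
    null_at = null.summary[null.summary["width_um"] == width]
    if null_at.empty:
        raise ValidationError(f"simulation null does not cover width {width}")
    patients = pd.DataFrame(
        [
            {
                "patient_id": s.patient_id,
                "median_F_N": s.median_F_N,
                "median_F_D": s.median_F_D,
            }
            for s in summaries
            if s.width_um == width
        ]
    )
    null_line = null_at[
        ["seed_count", "mean_F_N", "sd_F_N", "mean_F_D", "sd_F_D"]
    ].reset_index(drop=True)
    reps = null.per_replicate[null.per_replicate["width_um"] == width]
    pooled = pd.DataFrame(
        [
            {
                "mean_F_N": reps["F_N"].mean(),
                "sd_F_N": reps["F_N"].std(),
                "mean_F_D": reps["F_D"].mean(),
                "sd_F_D": reps["F_D"].std(),
            }
        ]
    )
    return {"patients": patients, "null_line": null_line, "pooled": pooled}
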