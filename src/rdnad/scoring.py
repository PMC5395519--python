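"""AD robustness score: compare two external-set accuracy curves produced by
the same AD expansion.

A trustworthy AD should (a) relate accuracy to its distance-to-model measure
the same way on two independent external sets, and (b) show accuracy
degrading as the AD expands.  The score walks the two cumulative curves
segment by segment: each segment pair receives a slope-mismatch penalty
(SMP — per-curve penalties of 1 for a falling segment, 2 for flat, 4 for
rising, multiplied together), weighted by the fraction of compounds the
segment adds, with the absolute accuracy gap |y_i - z_i| as a mild
coefficient.  The sum is divided by F_added, the fraction of combined data
added between the first and last iterations, which rewards resolution at the
model's core.  Lower is better; two identical, strictly falling curves score
exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datamodel import ADProfile

logger = logging.getLogger("rdnad.scoring")

__all__ = [
    "segment_slope_penalty",
    "pairwise_smp",
    "ad_score",
    "ad_score_from_profile",
    "ADScoreResult",
    "SegmentPenalty",
]

SLOPE_TOL = 1e-9


def segment_slope_penalty(m: float, tol: float = SLOPE_TOL) -> int:
    """Penalty for one curve segment's slope: 1 if falling, 2 if flat
    (|m| <= tol), 4 if rising."""
    if m < -tol:
        return 1
    if m > tol:
        return 4
    return 2


def pairwise_smp(m_y: float, m_z: float, tol: float = SLOPE_TOL) -> int:
    """Slope mismatch penalty of a matched segment pair: the product of the
    two per-curve penalties (1, 2, 4, 8 or 16)."""
    return segment_slope_penalty(m_y, tol) * segment_slope_penalty(m_z, tol)


@dataclass
class SegmentPenalty:
    """Per-segment scoring record (segments are indexed 2..P)."""

    index: int
    slope_y: float
    slope_z: float
    penalty_y: int
    penalty_z: int
    smp: int
    n_added: int
    wp: float
    accuracy_gap: float
    summand: float


@dataclass
class ADScoreResult:
    """The AD robustness score with its full per-segment breakdown.

    ``f_added`` is the difference form (combined coverage gained between the
    first and last iterations, over the combined total); ``f_added_total`` is
    the alternative reading (combined coverage at the last iteration) —
    reported for transparency, the score always uses the difference form.
    """

    score: float
    f_added: float
    f_added_total: float
    n_total: int
    segments: list[SegmentPenalty] = field(repr=False)


def _segment_summand(wp: float, accuracy_gap: float) -> float:
    # The accuracy-difference term enters as a coefficient of WP:
    # summand_i = WP_i * (1 + |y_i - z_i|).  Isolated here so any alternative
    # grouping can be swapped in and audited in one place.
    return wp * (1.0 + accuracy_gap)


def ad_score(
    counts_y,
    acc_y,
    counts_z,
    acc_z,
    n_total_y: int | None = None,
    n_total_z: int | None = None,
    tol: float = SLOPE_TOL,
) -> ADScoreResult:
    """Score two cumulative AD curves that share one iteration grid.

    Parameters
    ----------
    counts_y, counts_z:
        Cumulative included counts per iteration for datasets Y and Z.
    acc_y, acc_z:
        Cumulative accuracies per iteration (must be defined at every
        iteration scored).
    n_total_y, n_total_z:
        Dataset sizes; default to the final cumulative counts.
    tol:
        Slope magnitude below which a segment counts as flat.

    Slopes are taken on accuracy versus the combined cumulative fraction
    included (the standardized x-axis shared by all methods).  Segments that
    add no compounds get WP_i = 0 and contribute nothing.
    """
    counts_y = np.asarray(counts_y, dtype=int)
    counts_z = np.asarray(counts_z, dtype=int)
    acc_y = np.asarray(acc_y, dtype=float)
    acc_z = np.asarray(acc_z, dtype=float)
    P = len(counts_y)
    if not (len(counts_z) == len(acc_y) == len(acc_z) == P):
        raise ValueError("the two curves must share one iteration grid")
    if P < 2:
        raise ValueError("scoring needs at least 2 iterations")
    if np.isnan(acc_y).any() or np.isnan(acc_z).any():
        raise ValueError("curves must have defined accuracy at every scored iteration")
    if np.any(np.diff(counts_y) < 0) or np.any(np.diff(counts_z) < 0):
        raise ValueError("cumulative counts must be non-decreasing")
    n_total_y = int(counts_y[-1]) if n_total_y is None else int(n_total_y)
    n_total_z = int(counts_z[-1]) if n_total_z is None else int(n_total_z)
    n_total = n_total_y + n_total_z
    if n_total <= 0:
        raise ValueError("combined dataset size must be positive")

    combined = counts_y + counts_z
    x = combined / n_total
    f_added = float((combined[-1] - combined[0]) / n_total)
    f_added_total = float(combined[-1] / n_total)
    if f_added <= 0:
        raise ValueError("no instance added after the first iteration (F_added = 0)")

    segments: list[SegmentPenalty] = []
    total = 0.0
    for i in range(1, P):
        dx = x[i] - x[i - 1]
        dy, dz = acc_y[i] - acc_y[i - 1], acc_z[i] - acc_z[i - 1]
        if dx > 0:
            m_y, m_z = dy / dx, dz / dx
        else:  # no compounds added: WP = 0 regardless; slopes by accuracy change
            m_y = 0.0 if dy == 0 else np.sign(dy) * np.inf
            m_z = 0.0 if dz == 0 else np.sign(dz) * np.inf
        p_y = segment_slope_penalty(m_y, tol)
        p_z = segment_slope_penalty(m_z, tol)
        smp = p_y * p_z
        n_added = int(combined[i] - combined[i - 1])
        wp = smp * n_added / n_total
        gap = float(abs(acc_y[i] - acc_z[i]))
        summand = _segment_summand(wp, gap)
        total += summand
        segments.append(SegmentPenalty(
            index=i + 1, slope_y=float(m_y), slope_z=float(m_z),
            penalty_y=p_y, penalty_z=p_z, smp=smp, n_added=n_added,
            wp=wp, accuracy_gap=gap, summand=summand,
        ))
    return ADScoreResult(
        score=total / f_added,
        f_added=f_added,
        f_added_total=f_added_total,
        n_total=n_total,
        segments=segments,
    )


def ad_score_from_profile(
    profile: ADProfile,
    dataset_y: str | None = None,
    dataset_z: str | None = None,
    tol: float = SLOPE_TOL,
) -> ADScoreResult:
    """Score two datasets carried by one AD profile.

    Leading iterations where either dataset is still empty (undefined
    accuracy) are dropped before scoring.
    """
    datasets = profile.datasets
    if dataset_y is None or dataset_z is None:
        if len(datasets) != 2:
            raise ValueError("profile must carry exactly 2 datasets, or name them explicitly")
        dataset_y, dataset_z = datasets
    cy, cz = profile.counts(dataset_y), profile.counts(dataset_z)
    ay, az = profile.accuracies(dataset_y), profile.accuracies(dataset_z)
    defined = ~(np.isnan(ay) | np.isnan(az))
    if not defined.any():
        raise ValueError("no iteration has defined accuracy for both datasets")
    start = int(np.argmax(defined))
    if not defined[start:].all():
        raise ValueError("accuracy becomes undefined after being defined; invalid profile")
    return ad_score(
        cy[start:], ay[start:], cz[start:], az[start:],
        n_total_y=profile.dataset_sizes[dataset_y],
        n_total_z=profile.dataset_sizes[dataset_z],
        tol=tol,
    )
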