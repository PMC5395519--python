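"""ReliefF feature weighting for AD-specific descriptor selection.

ReliefF scores each descriptor by how well it separates the two classes
within local neighbourhoods: for every sampled instance the k nearest
same-class neighbours (hits) and k nearest other-class neighbours (misses)
are found, and a feature is rewarded when it differs across classes and
penalised when it differs within a class.  Correlated-but-relevant features
keep their full weight, which suits AD construction (correlated descriptors
can still cover different parts of chemical space).

Numeric diff is |a - b| / (max - min) with the range taken on the full
dataset; features are effectively scaled to [0, 1] internally, so weights
are invariant to positive rescaling of any descriptor.  Neighbour search
uses Manhattan distance on the scaled features, the conventional Relief
metric.  ``sigma`` controls optional exponential rank-based distance
weighting of the k neighbour contributions: the j-th nearest neighbour
(j = 1..k) receives influence proportional to exp(-(j / sigma)^2),
normalised to sum to one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("rdnad.relieff")

__all__ = ["FeatureWeights", "relieff_weights", "average_ranks", "select_top_k"]


@dataclass
class FeatureWeights:
    """Per-descriptor ReliefF weights with derived ranks (1 = best).

    Ties in weight are broken by lexicographic feature name, so ranks are
    always a permutation of 1..n_features.
    """

    names: list[str]
    weights: np.ndarray
    metadata: dict = field(default_factory=dict)
    ranks: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.names = [str(n) for n in self.names]
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.names) != len(self.weights):
            raise ValueError("names and weights must align")
        if not np.isfinite(self.weights).all():
            raise ValueError("weights must be finite")
        order = sorted(range(len(self.names)),
                       key=lambda i: (-self.weights[i], self.names[i]))
        self.ranks = np.empty(len(self.names), dtype=int)
        self.ranks[order] = np.arange(1, len(self.names) + 1)

    def ordered_names(self) -> list[str]:
        return [self.names[i] for i in np.argsort(self.ranks)]


def _neighbour_order(dist_row: np.ndarray, candidates: np.ndarray) -> np.ndarray:
    # stable (distance, index) ordering for deterministic ties
    return candidates[np.argsort(dist_row[candidates], kind="stable")]


def _rank_influence(k: int, sigma: float, weight_by_distance: bool) -> np.ndarray:
    if not weight_by_distance:
        return np.full(k, 1.0 / k)
    w = np.exp(-((np.arange(1, k + 1) / sigma) ** 2))
    return w / w.sum()


def relieff_weights(
    X,
    y,
    n_neighbors: int = 10,
    sigma: float = 2.0,
    weight_by_distance: bool = False,
    n_sample: int | None = None,
    seed: int | None = None,
    feature_names=None,
) -> FeatureWeights:
    """Standard binary-class ReliefF.

    Parameters
    ----------
    X, y:
        Descriptor matrix and binary labels; both classes need >= 2 members.
    n_neighbors:
        Hits and misses examined per sampled instance (clamped with a warning
        when a class is too small).
    sigma:
        Decay parameter of the exponential rank weighting, active when
        ``weight_by_distance`` is set.
    n_sample:
        Number of instances sampled (without replacement) as Relief anchors;
        ``None`` uses every instance in order, which is fully deterministic
        and needs no seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    n, p = X.shape
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(p)]
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("ReliefF needs two classes")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 instances")

    rng = np.random.default_rng(seed)
    span = X.max(axis=0) - X.min(axis=0)
    scale = np.where(span > 0, span, 1.0)  # constant features diff to exactly 0
    Xs = (X - X.min(axis=0)) / scale
    Xs[:, span == 0] = 0.0

    if n_sample is None or n_sample >= n:
        anchors = np.arange(n)
    else:
        anchors = rng.choice(n, size=n_sample, replace=False)
    m = len(anchors)

    # Manhattan distances on scaled features, computed blockwise
    weights = np.zeros(p)
    for i in anchors:
        d = np.abs(Xs - Xs[i]).sum(axis=1)
        hits_pool = np.flatnonzero((y == y[i]) & (np.arange(n) != i))
        miss_pool = np.flatnonzero(y != y[i])
        k_hit = min(n_neighbors, len(hits_pool))
        k_miss = min(n_neighbors, len(miss_pool))
        if k_hit < n_neighbors or k_miss < n_neighbors:
            logger.warning("n_neighbors clamped to (%d hits, %d misses) for instance %d",
                           k_hit, k_miss, i)
        hits = _neighbour_order(d, hits_pool)[:k_hit]
        misses = _neighbour_order(d, miss_pool)[:k_miss]
        infl_h = _rank_influence(k_hit, sigma, weight_by_distance)
        infl_m = _rank_influence(k_miss, sigma, weight_by_distance)
        diff_h = np.abs(Xs[hits] - Xs[i])    # (k_hit, p)
        diff_m = np.abs(Xs[misses] - Xs[i])  # (k_miss, p)
        # column-wise reductions (not matmul) so identical feature columns
        # accumulate identically regardless of their position
        hit_term = (diff_h * infl_h[:, None]).sum(axis=0)
        miss_term = (diff_m * infl_m[:, None]).sum(axis=0)
        weights += (miss_term - hit_term) / m

    return FeatureWeights(
        names=list(feature_names),
        weights=weights,
        metadata={"n_neighbors": n_neighbors, "sigma": sigma,
                  "weight_by_distance": weight_by_distance,
                  "n_sample": m, "seed": seed},
    )


def average_ranks(runs: list[FeatureWeights]) -> FeatureWeights:
    """Average feature ranks over repeated (subsampled) ReliefF runs.

    Returns a :class:`FeatureWeights` whose ``weights`` are *negated mean
    ranks* so the usual best-first ordering applies (rank 1 on top).
    """
    if not runs:
        raise ValueError("need at least one run")
    names = runs[0].names
    for r in runs[1:]:
        if r.names != names:
            raise ValueError("runs must cover identical feature sets")
    mean_rank = np.mean([r.ranks for r in runs], axis=0)
    return FeatureWeights(
        names=names,
        weights=-mean_rank,
        metadata={"n_runs": len(runs), "mean_rank": mean_rank},
    )


def select_top_k(weights: FeatureWeights, k: int = 20) -> list[str]:
    """The k best-ranked descriptor names (deterministic under ties)."""
    if k > len(weights.names):
        raise ValueError(f"k={k} exceeds the {len(weights.names)} available features")
    return weights.ordered_names()[:k]
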