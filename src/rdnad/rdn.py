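"""Reliability-density neighbourhood (RDN) applicability domain.

The method expands an AD outwards from the training data: at each iteration k
every training instance is given a neighbourhood radius derived from its
local density (average distance to its k nearest neighbours, bounded by the
Tukey outlier fence over the whole training set) and shrunk multiplicatively
by (a) a step-schedule factor that slows the expansion near the dense core
and (b) the instance's reliability weight W = (1 - STD) x agreement.  A query
compound is inside the AD once it falls within the radius of at least
``min_neighbors`` training instances.  Cumulative inclusion and cumulative
accuracy of external sets along the expansion form the AD profile.

dk-NN is the unweighted special case: W = 1 everywhere and no step scaling.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
from scipy.spatial.distance import cdist

from .datamodel import ADProfile, CoverageResult, LabeledDescriptorSet, ProfileIteration

logger = logging.getLogger("rdnad.rdn")

__all__ = [
    "DEFAULT_SCHEDULE",
    "pairwise_euclidean",
    "avg_knn_distance",
    "tukey_refval",
    "neighborhood_thresholds",
    "step_scale",
    "coverage_at_iteration",
    "rdn_profile",
    "dknn_profile",
]

#: Three-tier step schedule: radii scaled to 1/3 for k = 1-30 (slow expansion
#: through the dense core), 1/2 for k = 31-40, and used directly beyond k = 40.
DEFAULT_SCHEDULE: tuple[tuple[float, float], ...] = (
    (30, 1.0 / 3.0),
    (40, 0.5),
    (np.inf, 1.0),
)

#: Unit schedule — radii used as computed at every k (the dk-NN behaviour).
UNIT_SCHEDULE: tuple[tuple[float, float], ...] = ((np.inf, 1.0),)


def pairwise_euclidean(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Exact Euclidean distance matrix between the rows of A and B.

    Both matrices must live in the same standardized descriptor space."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.ndim != 2 or B.ndim != 2 or A.shape[1] != B.shape[1]:
        raise ValueError("matrices must be 2-D with matching column counts")
    return cdist(A, B, metric="euclidean")


def avg_knn_distance(distmat: np.ndarray, k: int) -> np.ndarray:
    """Per-instance mean distance to its k nearest training neighbours.

    ``distmat`` is the square training self-distance matrix; the self-distance
    is excluded.  Neighbours are chosen by stable sort on (distance, index) so
    ties at the k-th neighbour resolve deterministically; tied neighbours
    beyond the k-th are excluded.
    """
    distmat = np.asarray(distmat, dtype=float)
    n = distmat.shape[0]
    if distmat.shape != (n, n):
        raise ValueError("distmat must be square")
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n_train (got k={k}, n={n})")
    d = distmat.copy()
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")
    nearest = np.take_along_axis(d, order[:, :k], axis=1)
    return nearest.mean(axis=1)


def tukey_refval(values) -> float:
    """Tukey outlier fence Q3 + 1.5 x IQR of a list of average k-NN distances.

    Quartiles use linear interpolation between order statistics (the common
    "type 7" convention).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot compute a fence on an empty list")
    q1, q3 = np.percentile(values, [25, 75])
    return float(q3 + 1.5 * (q3 - q1))


def neighborhood_thresholds(distmat: np.ndarray, refval: float) -> np.ndarray:
    """Per-instance neighbourhood radius D_i: the mean distance to all
    training neighbours at distance <= RefVal (self excluded).

    An instance with no neighbour inside the fence gets D_i = 0 and
    contributes no coverage.
    """
    if refval < 0:
        raise ValueError("RefVal must be non-negative")
    d = np.asarray(distmat, dtype=float).copy()
    np.fill_diagonal(d, np.inf)
    within = d <= refval
    counts = within.sum(axis=1)
    sums = np.where(within, d, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        D = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return D


def _validate_schedule(schedule) -> tuple[tuple[float, float], ...]:
    sched = tuple((float(ub), float(f)) for ub, f in schedule)
    if not sched:
        raise ValueError("schedule must be non-empty")
    bounds = [ub for ub, _ in sched]
    if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
        raise ValueError("schedule k-upper-bounds must be strictly increasing")
    if any(f <= 0 for _, f in sched):
        raise ValueError("schedule factors must be positive")
    if not np.isinf(bounds[-1]):
        raise ValueError("last schedule entry must cover all k (upper bound inf)")
    return sched


def step_scale(k: int, schedule=DEFAULT_SCHEDULE) -> float:
    """Radius scale factor at neighbour count k under an ordered
    (k-upper-bound, factor) schedule."""
    if k < 1:
        raise ValueError("k must be >= 1")
    for upper, factor in _validate_schedule(schedule):
        if k <= upper:
            return factor
    raise AssertionError("unreachable: schedule ends at inf")


def coverage_at_iteration(
    ext_train_distmat: np.ndarray,
    effective_radii: np.ndarray,
    min_neighbors: int = 1,
) -> CoverageResult:
    """Coverage of query compounds by the training neighbourhoods.

    A query is included iff at least ``min_neighbors`` training instances
    cover it, where instance i covers queries at distance <= its effective
    radius (closed ball).  Equals a brute-force double loop exactly.
    """
    if min_neighbors < 1:
        raise ValueError("min_neighbors must be >= 1")
    dmat = np.asarray(ext_train_distmat, dtype=float)
    radii = np.asarray(effective_radii, dtype=float)
    if dmat.ndim != 2 or dmat.shape[1] != radii.shape[0]:
        raise ValueError("distance matrix columns must match the radii vector")
    counts = (dmat <= radii[np.newaxis, :]).sum(axis=1)
    return CoverageResult(included=counts >= min_neighbors, covering_counts=counts)


def _external_arrays(externals) -> dict[str, LabeledDescriptorSet]:
    if isinstance(externals, Mapping):
        named = dict(externals)
    elif isinstance(externals, LabeledDescriptorSet):
        named = {"external": externals}
    else:
        named = {f"ext{i + 1}": e for i, e in enumerate(externals)}
    for name, ds in named.items():
        if not isinstance(ds, LabeledDescriptorSet):
            raise TypeError(f"external {name!r} must be a LabeledDescriptorSet")
        if ds.correct is None:
            raise ValueError(f"external {name!r} needs correctness flags to profile accuracy")
    return named


def rdn_profile(
    train: LabeledDescriptorSet | np.ndarray,
    W: np.ndarray,
    externals,
    k_max: int = 65,
    schedule=DEFAULT_SCHEDULE,
    min_neighbors: int = 1,
    method_tag: str = "rdn",
) -> ADProfile:
    """Run the RDN expansion for k = 1..k_max and profile the external sets.

    Parameters
    ----------
    train:
        Standardized training descriptors (set or plain matrix).
    W:
        Per-training-instance reliability weights in [0, 1].
    externals:
        One or more standardized external sets carrying ``correct`` flags
        (mapping name -> set, a single set, or a sequence).
    k_max:
        Largest neighbour count scanned; must be < n_train.
    schedule:
        Ordered (k-upper-bound, factor) radius step schedule.
    min_neighbors:
        Minimum number of covering training instances for inclusion.

    At each k the per-instance average k-NN distance, the Tukey fence RefVal
    and the radii D_i are recomputed; radii are scaled by the schedule factor
    and by W.  Inclusion accumulates as the union over iterations 1..k and
    accuracy is the cumulative fraction of included compounds whose model
    prediction was correct.
    """
    Xt = train.X if isinstance(train, LabeledDescriptorSet) else np.asarray(train, dtype=float)
    n_train = Xt.shape[0]
    if k_max >= n_train:
        raise ValueError(f"k_max must be < n_train (got {k_max} >= {n_train})")
    W = np.asarray(W, dtype=float)
    if W.shape != (n_train,):
        raise ValueError("W must have one weight per training instance")
    if np.any((W < 0) | (W > 1)):
        raise ValueError("weights must lie in [0, 1]")
    sched = _validate_schedule(schedule)
    named = _external_arrays(externals)

    dist_tt = pairwise_euclidean(Xt, Xt)
    d = dist_tt.copy()
    np.fill_diagonal(d, np.inf)
    sorted_d = np.sort(d, axis=1)

    ext_dist = {name: pairwise_euclidean(ds.X, Xt) for name, ds in named.items()}
    included = {name: np.zeros(ds.n_compounds, dtype=bool) for name, ds in named.items()}
    first_iter = {name: np.zeros(ds.n_compounds, dtype=int) for name, ds in named.items()}

    iterations: list[ProfileIteration] = []
    for k in range(1, k_max + 1):
        avg_k = sorted_d[:, :k].mean(axis=1)
        refval = tukey_refval(avg_k)
        D = neighborhood_thresholds(dist_tt, refval)
        effective = D * step_scale(k, sched) * W

        n_inc: dict[str, int] = {}
        acc: dict[str, float | None] = {}
        for name, ds in named.items():
            cov = coverage_at_iteration(ext_dist[name], effective, min_neighbors)
            newly = cov.included & ~included[name]
            first_iter[name][newly] = k
            included[name] |= cov.included
            n = int(included[name].sum())
            n_inc[name] = n
            acc[name] = float(ds.correct[included[name]].mean()) if n else None
        iterations.append(ProfileIteration(index=k, threshold=float(k),
                                           n_included=n_inc, accuracy=acc))

    profile = ADProfile(
        method=method_tag,
        iterations=iterations,
        dataset_sizes={name: ds.n_compounds for name, ds in named.items()},
    )
    profile.first_inclusion = first_iter
    return profile


def dknn_profile(
    train,
    externals,
    k_max: int = 65,
    min_neighbors: int = 1,
) -> ADProfile:
    """Density k-NN AD: the RDN expansion with W = 1 everywhere and radii
    used as computed (unit step schedule)."""
    Xt = train.X if isinstance(train, LabeledDescriptorSet) else np.asarray(train, dtype=float)
    return rdn_profile(
        train,
        W=np.ones(Xt.shape[0]),
        externals=externals,
        k_max=k_max,
        schedule=UNIT_SCHEDULE,
        min_neighbors=min_neighbors,
        method_tag="dknn",
    )
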