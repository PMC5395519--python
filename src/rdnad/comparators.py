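"""Benchmark AD methods profiled alongside RDN.

* ``std_profile`` — accuracy across ensemble-STD tiers: the AD expands by
  raising an STD cutoff, so compounds with the most self-consistent ensemble
  predictions enter first.  Blind to systematic bias by construction.
* ``kde_profile`` — global density AD: a Gaussian kernel density estimate on
  the first principal component of the training descriptors; the AD expands
  by lowering a training-density percentile threshold.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
from sklearn.decomposition import PCA
from sklearn.neighbors import KernelDensity

from .datamodel import ADProfile, LabeledDescriptorSet, ProfileIteration

logger = logging.getLogger("rdnad.comparators")

__all__ = ["std_profile", "kde_profile", "silverman_bandwidth"]


def _named_arrays(values, template_name: str) -> dict[str, np.ndarray]:
    if isinstance(values, Mapping):
        return {str(k): np.asarray(v) for k, v in values.items()}
    return {template_name: np.asarray(values)}


def std_profile(
    ext_std,
    correct,
    tier_edges=None,
    max_default_edges: int = 50,
) -> ADProfile:
    """Cumulative accuracy across increasing ensemble-STD tiers.

    Parameters
    ----------
    ext_std:
        Per-compound ensemble STD values in [0, 1]; a single array or a
        mapping of dataset name -> array.
    correct:
        Matching model-correctness flags.
    tier_edges:
        Increasing STD cutoffs.  Default: the sorted unique STD values pooled
        across datasets, thinned evenly to at most ``max_default_edges``.

    A compound is inside the AD at edge e iff its STD <= e.
    """
    stds = _named_arrays(ext_std, "external")
    corr = _named_arrays(correct, "external")
    if set(stds) != set(corr):
        raise ValueError("STD and correctness datasets must match")
    for name, s in stds.items():
        if np.any((s < 0) | (s > 1)):
            raise ValueError(f"STD values for {name!r} must lie in [0, 1]")
        if len(corr[name]) != len(s):
            raise ValueError(f"correct flags for {name!r} must match the STD vector")

    if tier_edges is None:
        pooled = np.unique(np.concatenate(list(stds.values())))
        if len(pooled) > max_default_edges:
            idx = np.linspace(0, len(pooled) - 1, max_default_edges).round().astype(int)
            pooled = pooled[np.unique(idx)]
        tier_edges = pooled
    tier_edges = np.asarray(tier_edges, dtype=float)
    if tier_edges.size == 0:
        raise ValueError("tier_edges must be non-empty")
    if np.any(np.diff(tier_edges) <= 0):
        raise ValueError("tier_edges must be strictly increasing")

    included = {name: np.zeros(len(s), dtype=bool) for name, s in stds.items()}
    first_iter = {name: np.zeros(len(s), dtype=int) for name, s in stds.items()}
    iterations: list[ProfileIteration] = []
    for i, edge in enumerate(tier_edges, start=1):
        n_inc: dict[str, int] = {}
        acc: dict[str, float | None] = {}
        for name, s in stds.items():
            now = s <= edge
            newly = now & ~included[name]
            first_iter[name][newly] = i
            included[name] |= now
            n = int(included[name].sum())
            n_inc[name] = n
            acc[name] = float(np.asarray(corr[name])[included[name]].mean()) if n else None
        iterations.append(ProfileIteration(index=i, threshold=float(edge),
                                           n_included=n_inc, accuracy=acc))
    profile = ADProfile(
        method="std",
        iterations=iterations,
        dataset_sizes={name: len(s) for name, s in stds.items()},
    )
    profile.first_inclusion = first_iter
    return profile


def silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth for a 1-D Gaussian KDE."""
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < 2:
        raise ValueError("bandwidth selection needs at least 2 points")
    sd = np.std(x, ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        raise ValueError("zero-spread projection; cannot select a bandwidth")
    return float(0.9 * spread * n ** (-1 / 5))


def kde_profile(
    train: LabeledDescriptorSet | np.ndarray,
    externals,
    correct=None,
    bandwidth="auto",
    percentile_grid=None,
) -> ADProfile:
    """Density AD on the first principal component of the training set.

    PC1 is fitted on the (standardized) training matrix with its sign fixed
    so the largest-magnitude loading is positive; all sets are projected onto
    it and a Gaussian KDE is fitted to the training projection.  A compound is
    inside the AD at percentile p iff its density >= the p-th percentile of
    the training densities; the profile runs over a decreasing percentile
    grid (default 95, 90, ..., 5, 0).

    ``externals`` may be LabeledDescriptorSets with ``correct`` flags, or raw
    matrices paired with a matching ``correct`` mapping.
    """
    Xt = train.X if isinstance(train, LabeledDescriptorSet) else np.asarray(train, dtype=float)
    if Xt.shape[0] < 2:
        raise ValueError("KDE AD needs at least 2 training rows")
    if not Xt.std(axis=0).any():
        raise ValueError("zero-variance training matrix")

    if isinstance(externals, Mapping):
        named = dict(externals)
    elif isinstance(externals, LabeledDescriptorSet):
        named = {"external": externals}
    else:
        named = {f"ext{i + 1}": e for i, e in enumerate(externals)}
    ext_X: dict[str, np.ndarray] = {}
    ext_correct: dict[str, np.ndarray] = {}
    for name, e in named.items():
        if isinstance(e, LabeledDescriptorSet):
            if e.correct is None:
                raise ValueError(f"external {name!r} needs correctness flags")
            ext_X[name], ext_correct[name] = e.X, e.correct
        else:
            if correct is None or name not in correct:
                raise ValueError(f"raw-matrix external {name!r} needs correct flags")
            ext_X[name] = np.asarray(e, dtype=float)
            ext_correct[name] = np.asarray(correct[name]).astype(bool)

    pca = PCA(n_components=1)
    proj_train = pca.fit_transform(Xt).ravel()
    loading = pca.components_[0]
    if loading[np.argmax(np.abs(loading))] < 0:  # deterministic sign
        pca.components_ = -pca.components_
        proj_train = -proj_train

    h = silverman_bandwidth(proj_train) if bandwidth == "auto" else float(bandwidth)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    kde = KernelDensity(kernel="gaussian", bandwidth=h)
    kde.fit(proj_train[:, None])
    train_density = np.exp(kde.score_samples(proj_train[:, None]))

    if percentile_grid is None:
        percentile_grid = np.arange(95, -1, -5)
    percentile_grid = np.asarray(percentile_grid, dtype=float)
    if np.any(np.diff(percentile_grid) >= 0):
        raise ValueError("percentile_grid must be strictly decreasing")

    ext_density = {
        name: np.exp(kde.score_samples(pca.transform(X)[:, 0][:, None]))
        for name, X in ext_X.items()
    }
    included = {name: np.zeros(X.shape[0], dtype=bool) for name, X in ext_X.items()}
    first_iter = {name: np.zeros(X.shape[0], dtype=int) for name, X in ext_X.items()}
    iterations: list[ProfileIteration] = []
    for i, p in enumerate(percentile_grid, start=1):
        cutoff = np.percentile(train_density, p)
        n_inc: dict[str, int] = {}
        acc: dict[str, float | None] = {}
        for name in ext_X:
            now = ext_density[name] >= cutoff
            newly = now & ~included[name]
            first_iter[name][newly] = i
            included[name] |= now
            n = int(included[name].sum())
            n_inc[name] = n
            acc[name] = float(ext_correct[name][included[name]].mean()) if n else None
        iterations.append(ProfileIteration(index=i, threshold=float(p),
                                           n_included=n_inc, accuracy=acc))
    profile = ADProfile(
        method="kde",
        iterations=iterations,
        dataset_sizes={name: X.shape[0] for name, X in ext_X.items()},
    )
    profile.first_inclusion = first_iter
    return profile
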