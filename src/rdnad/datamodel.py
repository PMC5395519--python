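"""Shared domain types.

The package works on precomputed molecular descriptor matrices: one row per
compound, one column per descriptor, an observed binary class, and (for
external sets) a flag saying whether the deployed QSAR model predicted the
compound correctly.  No chemical structure parsing happens anywhere; these
containers are the boundary of the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger("rdnad.datamodel")

__all__ = [
    "LabeledDescriptorSet",
    "StandardizationParams",
    "fit_standardizer",
    "apply_standardizer",
    "ProfileIteration",
    "ADProfile",
    "CoverageResult",
]


@dataclass
class LabeledDescriptorSet:
    """Compounds x descriptors with IDs, observed class and optional
    model-correctness flags.

    Parameters
    ----------
    ids:
        Compound identifiers, one per row of ``X``.
    X:
        Real-valued descriptor matrix, shape ``(n_compounds, n_descriptors)``.
    feature_names:
        Unique descriptor names, one per column of ``X``.
    y_observed:
        Observed binary class per compound (0/1).
    correct:
        Optional boolean per compound: whether the external QSAR model
        predicted it correctly.  Needed to profile accuracy along an AD.
    """

    ids: list[str]
    X: np.ndarray
    feature_names: list[str]
    y_observed: np.ndarray
    correct: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        self.ids = [str(i) for i in self.ids]
        self.feature_names = [str(f) for f in self.feature_names]
        self.y_observed = np.asarray(self.y_observed)
        n, p = self.X.shape
        if len(self.ids) != n or len(self.y_observed) != n:
            raise ValueError("ids, X and y_observed must agree on row count")
        if len(self.feature_names) != p:
            raise ValueError("feature_names must match X column count")
        if len(set(self.feature_names)) != p:
            raise ValueError("descriptor names must be unique")
        if not np.isfinite(self.X).all():
            raise ValueError("X contains missing or non-finite values")
        if not np.isin(self.y_observed, (0, 1)).all():
            raise ValueError("y_observed must be binary (0/1)")
        self.y_observed = self.y_observed.astype(int)
        if self.correct is not None:
            self.correct = np.asarray(self.correct).astype(bool)
            if len(self.correct) != n:
                raise ValueError("correct flags must match row count")

    @property
    def n_compounds(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset_features(self, names: Sequence[str]) -> "LabeledDescriptorSet":
        """Return a copy restricted to the named descriptors, in that order."""
        idx = [self.feature_names.index(str(n)) for n in names]
        return LabeledDescriptorSet(
            ids=list(self.ids),
            X=self.X[:, idx].copy(),
            feature_names=[self.feature_names[i] for i in idx],
            y_observed=self.y_observed.copy(),
            correct=None if self.correct is None else self.correct.copy(),
        )


@dataclass
class StandardizationParams:
    """Per-descriptor mean and standard deviation estimated on a training set.

    Descriptors with zero training variance are dropped (their names are kept
    in ``dropped``) so distances never divide by zero.
    """

    feature_names: list[str]
    mean: np.ndarray
    sd: np.ndarray
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if not (self.sd > 0).all():
            raise ValueError("retained descriptors must have positive SD")


def fit_standardizer(train: LabeledDescriptorSet) -> StandardizationParams:
    """Estimate z-score parameters on a training set.

    Uses the sample SD (``ddof=1``) convention.  Zero-variance descriptors are
    dropped and logged; fitting an all-constant matrix is an error.
    """
    if train.n_compounds == 0:
        raise ValueError("cannot fit standardizer on an empty training set")
    mean = train.X.mean(axis=0)
    sd = train.X.std(axis=0, ddof=1) if train.n_compounds > 1 else np.zeros(train.n_features)
    keep = sd > 0
    dropped = [f for f, k in zip(train.feature_names, keep) if not k]
    if dropped:
        logger.warning("dropping %d zero-variance descriptor(s): %s", len(dropped), dropped)
    if not keep.any():
        raise ValueError("all descriptors have zero variance; nothing to standardize")
    names = [f for f, k in zip(train.feature_names, keep) if k]
    return StandardizationParams(names, mean[keep], sd[keep], dropped)


def apply_standardizer(
    params: StandardizationParams, dataset: LabeledDescriptorSet | np.ndarray
) -> np.ndarray:
    """Z-score a descriptor set with *training* parameters.

    External sets must always be transformed with the training-set params,
    never their own, so that distances are measured in one common space.
    """
    if isinstance(dataset, LabeledDescriptorSet):
        X = dataset.subset_features(params.feature_names).X
    else:
        X = np.asarray(dataset, dtype=float)
        if X.shape[1] != len(params.feature_names):
            raise ValueError("matrix column count does not match standardizer")
    return (X - params.mean) / params.sd


@dataclass
class ProfileIteration:
    """One step of an AD expansion.

    ``threshold`` is the method's own parameter at this step (k value, STD
    cutoff, or density percentile); counts and accuracies are cumulative and
    keyed by evaluated-dataset name.  An accuracy of ``None`` means undefined
    (no compound included yet) — never coded as zero.
    """

    index: int
    threshold: float
    n_included: dict[str, int]
    accuracy: dict[str, float | None]


@dataclass
class ADProfile:
    """Ordered iterations of an AD expansion for one or more datasets.

    Invariants: cumulative included counts are non-decreasing in the iteration
    index for every dataset, and accuracies lie in [0, 1] where defined.
    """

    method: str
    iterations: list[ProfileIteration]
    dataset_sizes: dict[str, int]
    # Iteration (1-based) at which each compound first entered the AD; 0 means
    # never included.  Populated by the profiling functions, not serialized.
    first_inclusion: dict[str, np.ndarray] | None = field(
        default=None, compare=False, repr=False
    )

    def __post_init__(self) -> None:
        if not self.iterations:
            raise ValueError("profile must contain at least one iteration")
        self.validate()

    def validate(self) -> None:
        datasets = set(self.dataset_sizes)
        prev = {d: 0 for d in datasets}
        for it in self.iterations:
            if set(it.n_included) != datasets or set(it.accuracy) != datasets:
                raise ValueError("iteration datasets do not match dataset_sizes")
            for d in datasets:
                n = it.n_included[d]
                if n < prev[d]:
                    raise ValueError(
                        f"cumulative included count decreases for dataset {d!r} "
                        f"at iteration {it.index} ({prev[d]} -> {n})"
                    )
                if n > self.dataset_sizes[d]:
                    raise ValueError(f"included count exceeds dataset size for {d!r}")
                acc = it.accuracy[d]
                if n == 0:
                    if acc is not None:
                        raise ValueError("accuracy must be undefined while count is 0")
                else:
                    if acc is None or not (0.0 <= acc <= 1.0):
                        raise ValueError("accuracy must lie in [0, 1] once defined")
                prev[d] = n

    @property
    def datasets(self) -> list[str]:
        return list(self.dataset_sizes)

    @property
    def n_iterations(self) -> int:
        return len(self.iterations)

    def counts(self, dataset: str) -> np.ndarray:
        return np.array([it.n_included[dataset] for it in self.iterations], dtype=int)

    def accuracies(self, dataset: str) -> np.ndarray:
        """Cumulative accuracy per iteration; NaN while undefined."""
        return np.array(
            [np.nan if it.accuracy[dataset] is None else it.accuracy[dataset]
             for it in self.iterations],
            dtype=float,
        )

    def fraction_included(self, dataset: str) -> np.ndarray:
        return self.counts(dataset) / self.dataset_sizes[dataset]

    def first_inclusion_fraction(self, dataset: str) -> np.ndarray:
        """Cumulative inclusion fraction of ``dataset`` at each compound's
        first-inclusion iteration; compounds never included get 1.0 (they lie
        at or beyond full coverage)."""
        if self.first_inclusion is None or dataset not in self.first_inclusion:
            raise ValueError(f"profile carries no first-inclusion record for {dataset!r}")
        first = self.first_inclusion[dataset]
        frac = self.fraction_included(dataset)
        out = np.ones(len(first), dtype=float)
        hit = first > 0
        out[hit] = frac[first[hit] - 1]
        return out


@dataclass
class CoverageResult:
    """Per-query coverage at one AD iteration: inclusion flag and the number
    of training neighbourhoods covering each query."""

    included: np.ndarray
    covering_counts: np.ndarray

    def __post_init__(self) -> None:
        self.included = np.asarray(self.included, dtype=bool)
        self.covering_counts = np.asarray(self.covering_counts, dtype=int)
        if self.included.shape != self.covering_counts.shape:
            raise ValueError("included and covering_counts must align")
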