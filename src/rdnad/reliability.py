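"""Ensemble-based prediction reliability: precision, bias, and their product.

A compound's prediction is *precise* when the members of a model ensemble
agree with each other (low ensemble standard deviation) and *unbiased* when
they agree with the observed class (high agreement).  The reliability weight

    W = (1 - STD) x agreement

combines both; it multiplies a training instance's neighbourhood radius in
the RDN applicability domain.  STD alone cannot see systematic bias: an
ensemble can be confidently, consistently wrong.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("rdnad.reliability")

__all__ = [
    "EnsemblePredictionMatrix",
    "ReliabilityWeight",
    "ensemble_std",
    "agreement_vote",
    "agreement_probability",
    "reliability_weight",
    "class_call",
    "bag_ensemble",
]


def class_call(prob):
    """Hard class call from a class-1 probability: class 1 iff p >= 0.5.

    Ties at exactly 0.5 go to class 1 (fixed, documented rule)."""
    return (np.asarray(prob, dtype=float) >= 0.5).astype(int)


def ensemble_std(row) -> float:
    """Sample standard deviation (denominator M-1) of one compound's M
    ensemble predictions.

    Predictions in [0, 1] keep the result in [0, 1]; values exceeding 1 by
    floating-point noise are clipped and logged.
    """
    row = np.asarray(row, dtype=float)
    if row.ndim != 1 or row.size < 2:
        raise ValueError("ensemble_std needs at least 2 member predictions")
    s = float(np.std(row, ddof=1))
    if s > 1.0:
        logger.warning("clipping ensemble STD %.17g to 1", s)
        s = 1.0
    return s


def agreement_vote(row, observed) -> float:
    """Fraction of ensemble members whose class call matches the observed
    class (the vote variant of agreement)."""
    row = np.asarray(row, dtype=float)
    observed = int(observed)
    if observed not in (0, 1):
        raise ValueError("observed class must be 0 or 1")
    return float(np.mean(class_call(row) == observed))


def agreement_probability(mean_prob, observed):
    """Probability variant of agreement: 1 - |observed - mean probability|.

    Used when per-member predictions are unavailable and only the ensemble
    mean probability is known.  More conservative than the vote variant: high
    agreement requires the mean probability itself to sit near the observed
    class, not merely on the right side of 0.5.
    """
    mean_prob = np.asarray(mean_prob, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if np.any((mean_prob < 0) | (mean_prob > 1)):
        raise ValueError("mean probability must lie in [0, 1]")
    if not np.isin(observed, (0, 1)).all():
        raise ValueError("observed class must be 0 or 1")
    out = 1.0 - np.abs(observed - mean_prob)
    return float(out) if out.ndim == 0 else out


def reliability_weight(std, agreement):
    """W = (1 - STD) x agreement; both factors and W lie in [0, 1]."""
    std = np.asarray(std, dtype=float)
    agreement = np.asarray(agreement, dtype=float)
    if np.any((std < 0) | (std > 1)) or np.any((agreement < 0) | (agreement > 1)):
        raise ValueError("STD and agreement must lie in [0, 1]")
    w = (1.0 - std) * agreement
    return float(w) if w.ndim == 0 else w


@dataclass
class EnsemblePredictionMatrix:
    """Per-compound predictions from an M-member ensemble.

    ``members`` holds class-1 probabilities (or hard 0/1 labels) with one
    column per ensemble member.  When member-level predictions are not
    available (e.g. only a repository-provided mean probability and STD),
    ``members`` may be ``None`` and ``mean_prob``/``std`` carry the supplied
    summaries instead.
    """

    ids: list[str]
    members: np.ndarray | None
    y_observed: np.ndarray
    yhat_model: np.ndarray | None = None
    mean_prob: np.ndarray | None = None
    std: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.y_observed = np.asarray(self.y_observed).astype(int)
        n = len(self.ids)
        if len(self.y_observed) != n:
            raise ValueError("y_observed must match ids")
        if not np.isin(self.y_observed, (0, 1)).all():
            raise ValueError("observed classes must be binary 0/1")
        if self.members is not None:
            self.members = np.asarray(self.members, dtype=float)
            if self.members.ndim != 2 or self.members.shape[0] != n:
                raise ValueError("members must be an (n_compounds, M) matrix")
            if self.members.shape[1] < 2:
                raise ValueError("an ensemble needs M >= 2 members")
            if np.any((self.members < 0) | (self.members > 1)):
                raise ValueError("member predictions must lie in [0, 1]")
            mean = self.members.mean(axis=1)
            if self.mean_prob is None:
                self.mean_prob = mean
            elif not np.allclose(self.mean_prob, mean):
                raise ValueError("supplied mean_prob disagrees with member mean")
        if self.members is None and self.mean_prob is None:
            raise ValueError("need member predictions or a mean probability")
        if self.mean_prob is not None:
            self.mean_prob = np.asarray(self.mean_prob, dtype=float)
        if self.std is not None:
            self.std = np.asarray(self.std, dtype=float)

    @property
    def n_compounds(self) -> int:
        return len(self.ids)

    @property
    def n_members(self) -> int:
        if self.members is None:
            raise ValueError("member-level predictions not available")
        return self.members.shape[1]

    def ensemble_std(self) -> np.ndarray:
        """Per-compound ensemble STD; uses supplied values when member-level
        predictions are absent."""
        if self.members is not None:
            return np.array([ensemble_std(r) for r in self.members])
        if self.std is None:
            raise ValueError("no member predictions and no supplied STD")
        return self.std

    def agreement(self, variant: str = "vote") -> np.ndarray:
        if variant == "vote":
            if self.members is None:
                raise ValueError("vote agreement needs member-level predictions")
            return np.array(
                [agreement_vote(r, y) for r, y in zip(self.members, self.y_observed)]
            )
        if variant == "probability":
            return np.asarray(agreement_probability(self.mean_prob, self.y_observed))
        raise ValueError(f"unknown agreement variant {variant!r}")

    def weights(self, variant: str = "vote") -> "ReliabilityWeight":
        std = self.ensemble_std()
        agr = self.agreement(variant)
        return ReliabilityWeight(std=std, agreement=agr,
                                 w=reliability_weight(std, agr), variant=variant)

    def model_correct(self) -> np.ndarray:
        """Whether the deployed model's class call matches the observed class;
        falls back to the ensemble mean probability when no single-model
        prediction was supplied."""
        if self.yhat_model is not None:
            calls = class_call(self.yhat_model)
        else:
            calls = class_call(self.mean_prob)
        return calls == self.y_observed


@dataclass
class ReliabilityWeight:
    """Per-compound STD, agreement and reliability weight W."""

    std: np.ndarray
    agreement: np.ndarray
    w: np.ndarray
    variant: str = "vote"

    def __post_init__(self) -> None:
        self.std = np.atleast_1d(np.asarray(self.std, dtype=float))
        self.agreement = np.atleast_1d(np.asarray(self.agreement, dtype=float))
        self.w = np.atleast_1d(np.asarray(self.w, dtype=float))
        for name, arr in (("std", self.std), ("agreement", self.agreement), ("w", self.w)):
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not np.allclose(self.w, (1 - self.std) * self.agreement):
            raise ValueError("W must equal (1 - STD) x agreement")
        if self.variant not in ("vote", "probability"):
            raise ValueError("variant must be 'vote' or 'probability'")


def _clone_learner(learner):
    try:
        from sklearn.base import clone

        return clone(learner)
    except Exception:
        return copy.deepcopy(learner)


def bag_ensemble(
    train,
    learner,
    n_models: int = 10,
    sample_frac: float = 0.8,
    replace: bool = True,
    seed: int | None = None,
    query=None,
):
    """Bootstrap-bagging harness producing an :class:`EnsemblePredictionMatrix`.

    Fits ``n_models`` clones of ``learner`` (anything with ``fit(X, y)`` and
    ``predict_proba``) on independent resamples of ``sample_frac`` of the
    training data, drawn with replacement by default.  Member class-1
    probabilities are collected for ``query`` (defaults to the training set
    itself, i.e. in-sample reliability).  A resample that contains a single
    class is redrawn (logged, at most 100 attempts).

    Fully reproducible under a fixed ``seed``.
    """
    from .datamodel import LabeledDescriptorSet  # local import avoids a cycle

    if not isinstance(train, LabeledDescriptorSet):
        raise TypeError("train must be a LabeledDescriptorSet")
    if n_models < 2:
        raise ValueError("an ensemble needs at least 2 models")
    if not (0 < sample_frac <= 1):
        raise ValueError("sample_frac must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    n = train.n_compounds
    n_draws = max(1, round(sample_frac * n))
    if query is None:
        query = train
    Xq = query.X if isinstance(query, LabeledDescriptorSet) else np.asarray(query, dtype=float)
    members = np.empty((Xq.shape[0], n_models), dtype=float)

    for m in range(n_models):
        for attempt in range(100):
            idx = rng.choice(n, size=n_draws, replace=replace)
            if len(np.unique(train.y_observed[idx])) > 1:
                break
            logger.info("resample %d attempt %d contained one class; redrawing", m, attempt)
        else:
            raise RuntimeError("could not draw a two-class resample in 100 attempts")
        model = _clone_learner(learner)
        model.fit(train.X[idx], train.y_observed[idx])
        proba = model.predict_proba(Xq)
        proba = np.asarray(proba)
        if proba.ndim != 2:
            raise TypeError("learner.predict_proba must return an (n, n_classes) array")
        classes = getattr(model, "classes_", np.array([0, 1]))
        col1 = int(np.where(np.asarray(classes) == 1)[0][0]) if 1 in classes else None
        members[:, m] = proba[:, col1] if col1 is not None else 0.0

    ids = query.ids if isinstance(query, LabeledDescriptorSet) else [str(i) for i in range(Xq.shape[0])]
    y_obs = query.y_observed if isinstance(query, LabeledDescriptorSet) else np.zeros(Xq.shape[0], dtype=int)
    return EnsemblePredictionMatrix(ids=list(ids), members=members, y_observed=y_obs)
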