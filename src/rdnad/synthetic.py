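"""Synthetic descriptor sets with planted density / reliability structure.

The generator emulates the situations an applicability domain must tell
apart in real QSAR data:

* a **dense, reliable core** — well-sampled chemistry the model predicts
  precisely and without bias;
* a **dense, systematically biased pocket** — compounds the ensemble agrees
  on *confidently but wrongly* (low STD, low agreement): the failure mode
  that defeats precision-only AD methods;
* a **sparse, noisy fringe** — thin data where both labels and predictions
  are erratic.

Each region is a Gaussian cluster in the informative features; noise
features carry no class signal.  Two external sets are drawn i.i.d. from the
same mixture as the training set — the robustness premise is that a useful
AD relates to predictive reliability the same way in training and external
data.  Ensemble prediction matrices are simulated directly with controlled
per-region precision (member dispersion) and bias (target mean probability
on the observed class), isolating AD logic from learner variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .datamodel import LabeledDescriptorSet
from .reliability import EnsemblePredictionMatrix, class_call

logger = logging.getLogger("rdnad.synthetic")

__all__ = [
    "RegionSpec",
    "SyntheticConfig",
    "SyntheticData",
    "default_config",
    "simulate_dataset",
    "simulate_ensemble_predictions",
    "simulate_study",
    "with_correctness",
]


@dataclass(frozen=True)
class RegionSpec:
    """One planted region of descriptor space.

    ``correct_prob`` is the target mean probability the ensemble assigns to
    the *observed* class (values below 0.5 plant systematic bias);
    ``dispersion`` is the member-to-member spread (low = high precision);
    ``flip_rate`` corrupts observed labels relative to the region's true
    class rule.
    """

    name: str
    center: float | Sequence[float]
    spread: float
    n_train: int
    n_external: int
    p_class1: float = 0.5
    flip_rate: float = 0.0
    dispersion: float = 0.05
    correct_prob: float = 0.9

    def __post_init__(self) -> None:
        if not 0 <= self.flip_rate <= 1:
            raise ValueError("flip_rate must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0 <= self.correct_prob <= 1:
            raise ValueError("correct_prob must lie in [0, 1]")
        if not 0 <= self.p_class1 <= 1:
            raise ValueError("p_class1 must lie in [0, 1]")
        if self.spread <= 0:
            raise ValueError("spread must be positive")


@dataclass(frozen=True)
class SyntheticConfig:
    regions: tuple[RegionSpec, ...]
    n_features: int = 5
    n_noise_features: int = 3
    n_members: int = 10

    def __post_init__(self) -> None:
        if not self.regions:
            raise ValueError("config must define at least one region")
        if len({r.name for r in self.regions}) != len(self.regions):
            raise ValueError("region names must be unique")
        if self.n_features < 1:
            raise ValueError("need at least one informative feature")
        if self.n_members < 2:
            raise ValueError("an ensemble needs at least 2 members")

    def region(self, name: str) -> RegionSpec:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)


def default_config() -> SyntheticConfig:
    """The three-region study configuration.

    Sizes and rates are chosen to look like a small, noisy binary QSAR
    campaign: a well-covered core carrying most of the data, a compact
    biased pocket (high precision, systematically wrong — the regime only
    the agreement term can catch), and a thin noisy fringe.
    """
    return SyntheticConfig(
        regions=(
            RegionSpec("core", center=0.0, spread=1.0, n_train=120, n_external=60,
                       flip_rate=0.02, dispersion=0.05, correct_prob=0.9),
            RegionSpec("biased", center=4.0, spread=0.6, n_train=25, n_external=20,
                       flip_rate=0.0, dispersion=0.02, correct_prob=0.1),
            RegionSpec("sparse", center=-5.0, spread=2.5, n_train=12, n_external=12,
                       flip_rate=0.25, dispersion=0.3, correct_prob=0.55),
        ),
        n_features=5,
        n_noise_features=3,
        n_members=10,
    )


@dataclass
class SyntheticData:
    """Training set plus two i.i.d. external sets, with per-row region labels
    keyed by split name ('train', 'external_1', 'external_2')."""

    train: LabeledDescriptorSet
    external_1: LabeledDescriptorSet
    external_2: LabeledDescriptorSet
    regions: dict[str, np.ndarray]
    config: SyntheticConfig
    #: uncorrupted class per row (observed labels are these, flipped at the
    #: region flip rate)
    true_labels: dict[str, np.ndarray] | None = None

    def __iter__(self) -> Iterator[LabeledDescriptorSet]:
        return iter((self.train, self.external_1, self.external_2))

    def split(self, name: str) -> LabeledDescriptorSet:
        return {"train": self.train, "external_1": self.external_1,
                "external_2": self.external_2}[name]


def _centroid(region: RegionSpec, n_features: int) -> np.ndarray:
    c = np.asarray(region.center, dtype=float)
    if c.ndim == 0:
        return np.full(n_features, float(c))
    if c.shape != (n_features,):
        raise ValueError(f"region {region.name!r}: center must be scalar or "
                         f"length-{n_features}")
    return c


def _draw_split(config: SyntheticConfig, rng: np.random.Generator,
                sizes_attr: str, split: str):
    rows, labels, truths, regions, ids = [], [], [], [], []
    p_total = config.n_features + config.n_noise_features
    for region in config.regions:
        n = getattr(region, sizes_attr)
        centroid = _centroid(region, config.n_features)
        X_inf = rng.normal(centroid, region.spread, size=(n, config.n_features))
        X_noise = rng.normal(0.0, 1.0, size=(n, config.n_noise_features))
        true = rng.binomial(1, region.p_class1, size=n)
        flips = rng.random(n) < region.flip_rate
        observed = np.where(flips, 1 - true, true)
        rows.append(np.hstack([X_inf, X_noise]))
        labels.append(observed)
        truths.append(true)
        regions.extend([region.name] * n)
        ids.extend(f"{region.name}_{split}_{j:04d}" for j in range(n))
    X = np.vstack(rows)
    assert X.shape[1] == p_total
    names = [f"desc_{j + 1}" for j in range(config.n_features)] + \
            [f"noise_{j + 1}" for j in range(config.n_noise_features)]
    dset = LabeledDescriptorSet(ids=ids, X=X, feature_names=names,
                                y_observed=np.concatenate(labels))
    return dset, np.asarray(regions), np.concatenate(truths)


def simulate_dataset(config: SyntheticConfig, seed: int | None = None) -> SyntheticData:
    """Draw a training set and two i.i.d. external sets from the configured
    region mixture.  Bit-identical under the same seed."""
    rng = np.random.default_rng(seed)
    train, r_train, t_train = _draw_split(config, rng, "n_train", "train")
    ext1, r1, t1 = _draw_split(config, rng, "n_external", "ext1")
    ext2, r2, t2 = _draw_split(config, rng, "n_external", "ext2")
    return SyntheticData(
        train=train, external_1=ext1, external_2=ext2,
        regions={"train": r_train, "external_1": r1, "external_2": r2},
        config=config,
        true_labels={"train": t_train, "external_1": t1, "external_2": t2},
    )


def simulate_ensemble_predictions(
    dataset: LabeledDescriptorSet,
    region_labels: np.ndarray,
    config: SyntheticConfig,
    M: int | None = None,
    seed: int | None = None,
    true_labels: np.ndarray | None = None,
) -> tuple[EnsemblePredictionMatrix, np.ndarray]:
    """Simulate an M-member ensemble prediction matrix for one split.

    Member class-1 probabilities are drawn Normal(mu, dispersion) around the
    region's target and truncated to [0, 1] by clipping, where mu is
    ``correct_prob`` re-expressed on the class-1 axis.  When ``true_labels``
    are given the target anchors on the *true* class — predictions track the
    underlying signal, so label flips become irreducible errors; otherwise it
    anchors on the observed class.  The returned correctness flags are True
    where the ensemble-mean class call matches the observed class; in biased
    regions (``correct_prob`` < 0.5) predictions are precise *and* wrong, so
    the flags come out False at near-zero STD.
    """
    rng = np.random.default_rng(seed)
    region_labels = np.asarray(region_labels)
    if len(region_labels) != dataset.n_compounds:
        raise ValueError("region labels must match the dataset rows")
    M = config.n_members if M is None else int(M)
    if M < 2:
        raise ValueError("an ensemble needs at least 2 members")
    anchor = dataset.y_observed if true_labels is None else np.asarray(true_labels).astype(int)
    if len(anchor) != dataset.n_compounds:
        raise ValueError("true_labels must match the dataset rows")

    n = dataset.n_compounds
    members = np.empty((n, M), dtype=float)
    for region in config.regions:
        mask = region_labels == region.name
        if not mask.any():
            continue
        y = anchor[mask]
        mu1 = np.where(y == 1, region.correct_prob, 1.0 - region.correct_prob)
        draws = rng.normal(mu1[:, None], region.dispersion, size=(mask.sum(), M))
        members[mask] = np.clip(draws, 0.0, 1.0)
    unknown = ~np.isin(region_labels, [r.name for r in config.regions])
    if unknown.any():
        raise ValueError(f"unknown region labels: {set(region_labels[unknown])}")

    epm = EnsemblePredictionMatrix(
        ids=list(dataset.ids), members=members, y_observed=dataset.y_observed
    )
    correct = class_call(epm.mean_prob) == dataset.y_observed
    return epm, correct


def simulate_study(config: SyntheticConfig | None = None, seed: int | None = None):
    """Run the full synthetic study setup: draw the datasets, standardize on
    the training set, simulate ensemble predictions for every split, and
    derive training reliability weights (vote agreement).

    Returns a dict with the pieces the AD methods consume:
    ``data``, ``params``, ``X_train`` (standardized), ``W`` (training
    reliability weights), and per-external-split dicts ``externals``
    (standardized :class:`LabeledDescriptorSet` with correctness flags) and
    ``ext_std`` (per-compound ensemble STD).  Sub-seeds for each split are
    derived deterministically from ``seed``.
    """
    from .datamodel import apply_standardizer, fit_standardizer

    if config is None:
        config = default_config()
    sub = np.random.SeedSequence(seed).generate_state(4)
    data = simulate_dataset(config, seed=int(sub[0]) % (2**31))

    params = fit_standardizer(data.train)
    X_train = apply_standardizer(params, data.train)
    epm_train, _ = simulate_ensemble_predictions(
        data.train, data.regions["train"], config,
        seed=int(sub[1]) % (2**31), true_labels=data.true_labels["train"])
    W = epm_train.weights("vote").w

    externals, ext_std = {}, {}
    for j, split in enumerate(("external_1", "external_2")):
        dset = data.split(split)
        epm, correct = simulate_ensemble_predictions(
            dset, data.regions[split], config,
            seed=int(sub[2 + j]) % (2**31), true_labels=data.true_labels[split])
        ext = with_correctness(dset, correct)
        ext.X = apply_standardizer(params, dset)
        ext.feature_names = list(params.feature_names)
        externals[split] = ext
        ext_std[split] = epm.ensemble_std()
    return {"data": data, "params": params, "X_train": X_train, "W": W,
            "externals": externals, "ext_std": ext_std,
            "epm_train": epm_train}


def with_correctness(dataset: LabeledDescriptorSet, correct: np.ndarray) -> LabeledDescriptorSet:
    """Copy of a descriptor set with model-correctness flags attached."""
    return LabeledDescriptorSet(
        ids=list(dataset.ids), X=dataset.X.copy(),
        feature_names=list(dataset.feature_names),
        y_observed=dataset.y_observed.copy(),
        correct=np.asarray(correct).astype(bool),
    )
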