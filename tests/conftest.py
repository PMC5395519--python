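import numpy as np
import pytest

from rdnad import (
    ADProfile,
    LabeledDescriptorSet,
    ProfileIteration,
    default_config,
    simulate_study,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def small_set():
    """Five compounds, three descriptors, mixed classes."""
    rng = np.random.default_rng(42)
    return LabeledDescriptorSet(
        ids=[f"c{i}" for i in range(5)],
        X=rng.normal(size=(5, 3)),
        feature_names=["mw", "logp", "tpsa"],
        y_observed=[0, 1, 0, 1, 1],
        correct=[True, True, False, True, False],
    )


@pytest.fixture(scope="session")
def study():
    """One full synthetic study (datasets, weights, standardized sets)."""
    return simulate_study(default_config(), seed=11)


def make_profile(counts_by_ds, acc_by_ds, sizes, method="rdn", thresholds=None):
    """Assemble an ADProfile from parallel per-dataset arrays."""
    datasets = list(sizes)
    P = len(next(iter(counts_by_ds.values())))
    iters = []
    for i in range(P):
        iters.append(ProfileIteration(
            index=i + 1,
            threshold=float(thresholds[i]) if thresholds is not None else float(i + 1),
            n_included={d: int(counts_by_ds[d][i]) for d in datasets},
            accuracy={d: (None if acc_by_ds[d][i] is None else float(acc_by_ds[d][i]))
                      for d in datasets},
        ))
    return ADProfile(method=method, iterations=iters, dataset_sizes=dict(sizes))
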