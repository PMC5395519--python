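"""RDN core: distances, Tukey fence, radii, step schedule, coverage,
profiles, and the dk-NN reduction."""

import numpy as np
import pytest

from rdnad import (
    DEFAULT_SCHEDULE,
    UNIT_SCHEDULE,
    LabeledDescriptorSet,
    avg_knn_distance,
    coverage_at_iteration,
    dknn_profile,
    neighborhood_thresholds,
    pairwise_euclidean,
    rdn_profile,
    step_scale,
    tukey_refval,
)

LINE = np.array([[0.0], [1.0], [3.0]])  # points on a line at 0, 1, 3


def brute_force_coverage(ext_train_dist, radii, min_neighbors):
    """Independent double-loop oracle: no vectorisation, no indexing."""
    included, counts = [], []
    for qrow in ext_train_dist:
        c = 0
        for d, r in zip(qrow, radii):
            if d <= r:
                c += 1
        counts.append(c)
        included.append(c >= min_neighbors)
    return np.array(included), np.array(counts)


class TestDistances:
    def test_identical_rows_zero(self):
        A = np.array([[1.0, 2.0]])
        assert pairwise_euclidean(A, A)[0, 0] == 0.0

    def test_3_4_5_triangle(self):
        d = pairwise_euclidean(np.array([[0.0, 0.0]]), np.array([[3.0, 4.0]]))
        assert d[0, 0] == 5.0

    def test_symmetry(self, rng):
        A = rng.normal(size=(6, 4))
        D = pairwise_euclidean(A, A)
        np.testing.assert_allclose(D, D.T)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            pairwise_euclidean(np.zeros((2, 3)), np.zeros((2, 4)))


class TestAvgKnnDistance:
    def test_line_k1(self):
        D = pairwise_euclidean(LINE, LINE)
        np.testing.assert_allclose(avg_knn_distance(D, 1), [1, 1, 2])

    def test_line_k2(self):
        D = pairwise_euclidean(LINE, LINE)
        np.testing.assert_allclose(avg_knn_distance(D, 2), [2, 1.5, 2.5])

    def test_duplicates_give_zero(self):
        pts = np.array([[0.0], [0.0], [5.0]])
        D = pairwise_euclidean(pts, pts)
        assert avg_knn_distance(D, 1)[0] == 0.0 and avg_knn_distance(D, 1)[1] == 0.0

    def test_monotone_in_k(self, rng):
        X = rng.normal(size=(15, 3))
        D = pairwise_euclidean(X, X)
        prev = avg_knn_distance(D, 1)
        for k in range(2, 15):
            cur = avg_knn_distance(D, k)
            assert (cur >= prev - 1e-12).all()
            prev = cur

    def test_k_bounds(self):
        D = pairwise_euclidean(LINE, LINE)
        with pytest.raises(ValueError):
            avg_knn_distance(D, 3)


class TestTukeyRefval:
    def test_constant_list(self):
        assert tukey_refval([4.2] * 7) == pytest.approx(4.2)

    def test_one_to_eight_linear_interpolation(self):
        # Q1 = 2.75, Q3 = 6.25 under type-7 quartiles -> 6.25 + 1.5*3.5
        assert tukey_refval(np.arange(1, 9)) == pytest.approx(11.5)

    def test_extreme_value_keeps_fence_above_q3(self, rng):
        vals = np.concatenate([rng.uniform(0, 1, 20), [1000.0]])
        ref = tukey_refval(vals)
        assert np.isfinite(ref) and ref >= np.percentile(vals, 75)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tukey_refval([])


class TestNeighborhoodThresholds:
    def test_line_refval_2(self):
        D = pairwise_euclidean(LINE, LINE)
        np.testing.assert_allclose(neighborhood_thresholds(D, 2.0), [1, 1.5, 2])

    def test_refval_below_all_distances(self):
        D = pairwise_euclidean(LINE, LINE)
        np.testing.assert_allclose(neighborhood_thresholds(D, 0.5), [0, 0, 0])

    def test_refval_above_all_distances(self, rng):
        X = rng.normal(size=(8, 2))
        D = pairwise_euclidean(X, X)
        got = neighborhood_thresholds(D, D.max() + 1)
        mask = ~np.eye(8, dtype=bool)
        expected = np.array([D[i][mask[i]].mean() for i in range(8)])
        np.testing.assert_allclose(got, expected)


class TestStepScale:
    @pytest.mark.parametrize("k, factor", [
        (1, 1 / 3), (10, 1 / 3), (30, 1 / 3),
        (31, 0.5), (35, 0.5), (40, 0.5),
        (41, 1.0), (50, 1.0), (65, 1.0),
    ])
    def test_default_three_tier_schedule(self, k, factor):
        assert step_scale(k, DEFAULT_SCHEDULE) == pytest.approx(factor)

    def test_override_schedule(self):
        assert step_scale(5, [(10, 0.25), (np.inf, 1.0)]) == 0.25

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            step_scale(5, [(10, 0.5), (5, 1.0), (np.inf, 1.0)])  # non-monotone
        with pytest.raises(ValueError):
            step_scale(5, [(10, -0.5), (np.inf, 1.0)])  # non-positive factor


class TestCoverage:
    def test_coincident_query_included(self):
        dist = np.array([[0.0, 5.0]])
        cov = coverage_at_iteration(dist, np.array([0.5, 0.5]), 1)
        assert cov.included[0]

    def test_all_zero_radii_include_nothing(self, rng):
        dist = rng.uniform(0.1, 5, size=(6, 4))
        cov = coverage_at_iteration(dist, np.zeros(4), 1)
        assert not cov.included.any()

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            dist = rng.uniform(0, 3, size=(20, 10))
            radii = rng.uniform(0, 2, size=10)
            mn = int(rng.integers(1, 4))
            cov = coverage_at_iteration(dist, radii, mn)
            inc, cnt = brute_force_coverage(dist, radii, mn)
            np.testing.assert_array_equal(cov.included, inc)
            np.testing.assert_array_equal(cov.covering_counts, cnt)

    def test_min_neighbors_validated(self):
        with pytest.raises(ValueError):
            coverage_at_iteration(np.zeros((1, 1)), np.zeros(1), 0)


def _random_inputs(rng, n_train=25, n_ext=15, p=3):
    Xt = rng.normal(size=(n_train, p))
    ext = LabeledDescriptorSet(
        ids=[f"q{i}" for i in range(n_ext)],
        X=rng.normal(size=(n_ext, p)),
        feature_names=[f"f{j}" for j in range(p)],
        y_observed=rng.integers(0, 2, n_ext),
        correct=rng.random(n_ext) < 0.7,
    )
    return Xt, ext


class TestProfiles:
    def test_reduction_to_dknn(self, rng):
        Xt, ext = _random_inputs(rng)
        W = np.ones(len(Xt))
        a = rdn_profile(Xt, W, {"e": ext}, k_max=8, schedule=UNIT_SCHEDULE)
        b = dknn_profile(Xt, {"e": ext}, k_max=8)
        assert a.iterations == b.iterations
        assert a.dataset_sizes == b.dataset_sizes

    def test_all_zero_weights_empty_ad(self, rng):
        Xt, ext = _random_inputs(rng)
        prof = rdn_profile(Xt, np.zeros(len(Xt)), {"e": ext}, k_max=5)
        assert all(it.n_included["e"] == 0 for it in prof.iterations)
        assert all(it.accuracy["e"] is None for it in prof.iterations)

    def test_cumulative_inclusion_non_decreasing(self, rng):
        Xt, ext = _random_inputs(rng)
        W = rng.uniform(0, 1, len(Xt))
        prof = rdn_profile(Xt, W, {"e": ext}, k_max=12)
        counts = prof.counts("e")
        assert (np.diff(counts) >= 0).all()

    def test_lowering_one_weight_never_expands_coverage(self, rng):
        Xt, ext = _random_inputs(rng)
        W = rng.uniform(0.3, 1, len(Xt))
        base = rdn_profile(Xt, W, {"e": ext}, k_max=6)
        W2 = W.copy()
        W2[int(rng.integers(len(W)))] *= 0.2
        less = rdn_profile(Xt, W2, {"e": ext}, k_max=6)
        for it_b, it_l in zip(base.iterations, less.iterations):
            assert it_l.n_included["e"] <= it_b.n_included["e"]

    def test_min_neighbors_subset(self, rng):
        Xt, ext = _random_inputs(rng, n_train=30, n_ext=20)
        W = rng.uniform(0.5, 1, len(Xt))
        p1 = rdn_profile(Xt, W, {"e": ext}, k_max=8, min_neighbors=1)
        p3 = rdn_profile(Xt, W, {"e": ext}, k_max=8, min_neighbors=3)
        for a, b in zip(p3.iterations, p1.iterations):
            assert a.n_included["e"] <= b.n_included["e"]

    def test_k_max_validated(self, rng):
        Xt, ext = _random_inputs(rng, n_train=10)
        with pytest.raises(ValueError):
            rdn_profile(Xt, np.ones(10), {"e": ext}, k_max=10)

    def test_first_inclusion_stable_under_extension(self, rng):
        Xt, ext = _random_inputs(rng)
        W = rng.uniform(0, 1, len(Xt))
        short = rdn_profile(Xt, W, {"e": ext}, k_max=5)
        long = rdn_profile(Xt, W, {"e": ext}, k_max=10)
        fs, fl = short.first_inclusion["e"], long.first_inclusion["e"]
        seen = fs > 0
        np.testing.assert_array_equal(fs[seen], fl[seen])

    def test_externals_require_correct_flags(self, rng):
        Xt, ext = _random_inputs(rng)
        ext.correct = None
        with pytest.raises(ValueError, match="correctness"):
            rdn_profile(Xt, np.ones(len(Xt)), {"e": ext}, k_max=4)
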