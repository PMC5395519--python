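"""Ensemble STD, the two agreement variants, W, and the bagging harness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rdnad import (
    EnsemblePredictionMatrix,
    LabeledDescriptorSet,
    agreement_probability,
    agreement_vote,
    bag_ensemble,
    ensemble_std,
    reliability_weight,
)


class TestEnsembleStd:
    @pytest.mark.parametrize("row, expected", [
        ([0.4, 0.4, 0.4], 0.0),                      # identical predictions
        ([1, 0, 1, 0], 0.5773502691896257),          # sqrt(1/3)
        ([1] * 5 + [0] * 5, 0.5270462766947299),     # sqrt(2.5/9)
    ])
    def test_hand_values(self, row, expected):
        assert ensemble_std(row) == pytest.approx(expected, abs=1e-10)

    def test_needs_two_members(self):
        with pytest.raises(ValueError):
            ensemble_std([0.5])

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30))
    @settings(max_examples=200, deadline=None)
    def test_bounded_by_one_for_unit_interval_predictions(self, row):
        assert 0.0 <= ensemble_std(row) <= 1.0


class TestAgreement:
    def test_vote_counts_correct_members(self):
        assert agreement_vote([1, 1, 0, 1, 0], observed=1) == pytest.approx(0.6)

    def test_vote_extremes(self):
        assert agreement_vote([1, 1, 1], observed=1) == 1.0
        assert agreement_vote([1, 1, 1], observed=0) == 0.0

    def test_probability_variant_worked_example(self):
        # mean ensemble probability 0.23 for an observed class of 0
        assert agreement_probability(0.23, 0) == pytest.approx(0.77)

    def test_probability_variant_extremes_and_symmetry(self):
        assert agreement_probability(1.0, 1) == 1.0
        assert agreement_probability(0.5, 0) == agreement_probability(0.5, 1) == 0.5

    def test_probability_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            agreement_probability(1.2, 1)

    def test_variants_coincide_on_hard_calls(self):
        # members that output hard 0/1 equal to their class calls: the mean
        # probability is the fraction voting 1, so both variants agree
        members = np.array([1, 1, 0, 1], dtype=float)
        vote = agreement_vote(members, observed=1)
        prob = agreement_probability(members.mean(), observed=1)
        assert vote == pytest.approx(prob)


class TestReliabilityWeight:
    def test_low_reliability_scenario(self):
        w = reliability_weight(0.70, 0.35)
        assert w == pytest.approx(0.105)
        assert 1 - w == pytest.approx(0.895)  # an 89.5% radius reduction

    def test_high_reliability_scenario(self):
        w = reliability_weight(0.01, 0.99)
        assert round(w * 100) == 98  # 98% reliability, a 2% reduction

    def test_identity(self):
        assert reliability_weight(0.0, 1.0) == 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            reliability_weight(-0.1, 0.5)

    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_both_factors(self, std, agreement, other):
        w = reliability_weight(std, agreement)
        assert 0.0 <= w <= 1.0
        # non-increasing in STD
        hi_std = max(std, other)
        assert reliability_weight(hi_std, agreement) <= reliability_weight(min(std, other), agreement) + 1e-12
        # non-decreasing in agreement
        hi_agr = max(agreement, other)
        assert reliability_weight(std, hi_agr) >= reliability_weight(std, min(agreement, other)) - 1e-12


class _ConstantOne:
    """Learner that always predicts class 1 with certainty."""

    classes_ = np.array([0, 1])

    def fit(self, X, y):
        return self

    def predict_proba(self, X):
        return np.column_stack([np.zeros(len(X)), np.ones(len(X))])

    def get_params(self, deep=True):
        return {}

    def set_params(self, **kw):
        return self


def _train_set(n=30, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 3))
    y = (X[:, 0] > 0).astype(int)
    return LabeledDescriptorSet(ids=[str(i) for i in range(n)], X=X,
                                feature_names=["a", "b", "c"], y_observed=y)


class TestBagEnsemble:
    def test_constant_learner_degenerate(self):
        train = _train_set()
        epm = bag_ensemble(train, _ConstantOne(), n_models=5, seed=3)
        rw = epm.weights("vote")
        np.testing.assert_allclose(rw.std, 0.0)
        np.testing.assert_array_equal(rw.agreement, (train.y_observed == 1).astype(float))

    def test_same_seed_reproduces(self):
        from sklearn.tree import DecisionTreeClassifier

        train = _train_set(40, seed=1)
        a = bag_ensemble(train, DecisionTreeClassifier(random_state=0), seed=9)
        b = bag_ensemble(train, DecisionTreeClassifier(random_state=0), seed=9)
        np.testing.assert_array_equal(a.members, b.members)

    def test_resample_size_is_80_percent(self):
        train = _train_set(100, seed=2)

        class _Recorder(_ConstantOne):
            sizes = []

            def fit(self, X, y):
                _Recorder.sizes.append(len(X))
                return self

        bag_ensemble(train, _Recorder(), n_models=10, sample_frac=0.8, seed=5)
        assert _Recorder.sizes == [80] * 10

    def test_query_set_predictions(self):
        from sklearn.tree import DecisionTreeClassifier

        train = _train_set(40, seed=1)
        query = _train_set(10, seed=7)
        epm = bag_ensemble(train, DecisionTreeClassifier(random_state=0),
                           seed=9, query=query)
        assert epm.members.shape == (10, 10)
        assert epm.ids == query.ids


class TestEnsemblePredictionMatrix:
    def test_mean_prob_is_row_mean(self):
        epm = EnsemblePredictionMatrix(ids=["a", "b"], members=[[0.2, 0.4], [1.0, 0.0]],
                                       y_observed=[0, 1])
        np.testing.assert_allclose(epm.mean_prob, [0.3, 0.5])

    def test_single_member_rejected(self):
        with pytest.raises(ValueError, match="M >= 2"):
            EnsemblePredictionMatrix(ids=["a"], members=[[0.5]], y_observed=[0])

    def test_weights_table_consistent(self):
        epm = EnsemblePredictionMatrix(ids=["a", "b"],
                                       members=[[0.9, 0.8, 1.0], [0.1, 0.0, 0.2]],
                                       y_observed=[1, 1])
        rw = epm.weights("vote")
        np.testing.assert_allclose(rw.w, (1 - rw.std) * rw.agreement)
        assert rw.agreement[0] == 1.0 and rw.agreement[1] == 0.0
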