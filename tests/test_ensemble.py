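"""Boosting arithmetic, voting rules and the rotation-boost classifier."""
import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp
from sklearn.neighbors import KNeighborsClassifier
from sklearn.metrics import f1_score

from rega.ensemble import (
    RotationBoostClassifier,
    compute_beta,
    init_weights,
    update_weights,
    weighted_bootstrap,
    weighted_error,
)
from rega.synthetic import SyntheticSpec, generate_planted_dataset


class TestWeightArithmetic:
    def test_init_uniform(self):
        np.testing.assert_allclose(init_weights(4), [0.25] * 4)
        np.testing.assert_allclose(init_weights(1), [1.0])

    def test_init_needs_samples(self):
        with pytest.raises(ValueError):
            init_weights(0)

    def test_weighted_error_hand_sum(self):
        w = np.array([0.1, 0.2, 0.3, 0.4])
        pred = np.array([0, 1, 0, 1])
        labels = np.array([0, 0, 0, 0])  # rows 2 and 4 (1-indexed) wrong
        assert weighted_error(pred, labels, w) == pytest.approx(0.6)

    def test_weighted_error_extremes(self):
        w = init_weights(3)
        y = np.array([1, 0, 1])
        assert weighted_error(y, y, w) == 0.0
        assert weighted_error(1 - y, y, w) == pytest.approx(1.0)

    @pytest.mark.parametrize("eps,beta", [(0.25, 1 / 3), (1 / 3, 0.5)])
    def test_beta_closed_form(self, eps, beta):
        assert compute_beta(eps) == pytest.approx(beta)
        assert np.log(1 / compute_beta(0.25)) == pytest.approx(np.log(3))

    @pytest.mark.parametrize("eps", [0.0, 0.5, 0.9, -0.1])
    def test_beta_guard(self, eps):
        with pytest.raises(ValueError):
            compute_beta(eps)

    def test_update_worked_case(self):
        w = np.full(3, 1 / 3)
        out = update_weights(w, 0.5, np.array([0.0, 0.0, 1.0]))
        np.testing.assert_allclose(out, [0.25, 0.25, 0.5])

    def test_update_all_correct_is_identity(self):
        w = np.array([0.2, 0.3, 0.5])
        np.testing.assert_allclose(update_weights(w, 0.4, np.zeros(3)), w)

    def test_update_matches_elementwise_oracle(self):
        # brute-force per-element evaluation on 100 random (w, l, beta) triples
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(2, 20))
            w = rng.random(n)
            w /= w.sum()
            miss = rng.integers(0, 2, n).astype(float)
            beta = float(rng.uniform(0.01, 0.99))
            oracle = np.array([w[j] * beta ** (1 - miss[j]) for j in range(n)])
            oracle /= sum(w[i] * beta ** (1 - miss[i]) for i in range(n))
            np.testing.assert_allclose(update_weights(w, beta, miss), oracle,
                                       atol=1e-12)

    @given(w=hnp.arrays(float, st.integers(2, 12),
                        elements=st.floats(0.01, 1.0)),
           beta=st.floats(0.01, 0.99),
           data=st.data())
    def test_update_invariants(self, w, beta, data):
        """Weights stay a distribution; wrong rows gain, right rows shrink."""
        w = w / w.sum()
        miss = np.array(data.draw(st.lists(
            st.sampled_from([0.0, 1.0]), min_size=len(w), max_size=len(w))))
        out = update_weights(w, beta, miss)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)
        assert (out >= 0).all()
        if 0 < miss.sum() < len(miss):  # eps strictly inside (0,1)
            assert (out[miss == 1] > w[miss == 1] - 1e-15).all()
            assert (out[miss == 0] < w[miss == 0] + 1e-15).all()

    def test_bootstrap_degenerate_distribution(self):
        rng = np.random.default_rng(0)
        idx = weighted_bootstrap(5, np.array([1.0, 0.0, 0.0]), rng)
        assert (idx == 0).all() and len(idx) == 5

    def test_bootstrap_binomial_concentration(self):
        rng = np.random.default_rng(1)
        n, k = 20000, 5
        idx = weighted_bootstrap(n, np.full(k, 1 / k), rng)
        counts = np.bincount(idx, minlength=k)
        sigma = np.sqrt(n * (1 / k) * (1 - 1 / k))
        assert np.abs(counts - n / k).max() < 4 * sigma


def _ensemble_with(betas, votes):
    """A RotationBoostClassifier with stubbed slots casting fixed votes."""
    class _Stub:
        def __init__(self, vote):
            self.vote = vote

        def predict(self, X):
            return np.full(X.shape[0], self.vote, dtype=int)

    class _IdRot:
        def transform(self, X):
            return X

    clf = RotationBoostClassifier()
    clf.classes_ = np.array([0, 1])
    clf.fallback_label_ = 0
    clf.n_features_in_ = 1
    from rega.ensemble import WeakLearnerSlot
    clf.slots_ = [WeakLearnerSlot(_IdRot(), _Stub(v), beta / (1 + beta), beta)
                  for beta, v in zip(betas, votes)]
    return clf


class TestVoting:
    def test_single_slot_is_base_prediction(self):
        clf = _ensemble_with([0.5], [1])
        assert clf.predict(np.zeros((3, 1))).tolist() == [1, 1, 1]

    def test_worked_support_case(self):
        # beta (0.5, 0.5, 1/3) voting (1,1,0): mu1 = 2 ln2 > mu0 = ln3
        clf = _ensemble_with([0.5, 0.5, 1 / 3], [1, 1, 0])
        X = np.zeros((1, 1))
        assert clf.predict(X).tolist() == [1]
        assert clf.decision_function(X)[0] == pytest.approx(
            2 * np.log(2) - np.log(3))

    def test_exact_tie_breaks_to_zero(self):
        clf = _ensemble_with([0.5, 0.5], [1, 0])
        X = np.zeros((2, 1))
        assert clf.decision_function(X)[0] == pytest.approx(0.0, abs=1e-15)
        assert clf.predict(X).tolist() == [0, 0]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_support_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(1, 6))
        betas = rng.uniform(0.05, 0.95, k)
        votes = rng.integers(0, 2, k)
        clf = _ensemble_with(list(betas), list(votes))
        mu = {0: 0.0, 1: 0.0}
        for beta, v in zip(betas, votes):
            mu[int(v)] += np.log(1 / beta)
        expected = 1 if mu[1] > mu[0] else 0
        assert clf.predict(np.zeros((1, 1)))[0] == expected
        assert clf.decision_function(np.zeros((1, 1)))[0] == pytest.approx(
            mu[1] - mu[0])

    def test_score_sign_consistent_with_labels(self):
        rng = np.random.default_rng(3)
        for seed in range(10):
            k = int(rng.integers(1, 7))
            clf = _ensemble_with(list(rng.uniform(0.05, 0.95, k)),
                                 list(rng.integers(0, 2, k)))
            X = np.zeros((1, 1))
            score, label = clf.decision_function(X)[0], clf.predict(X)[0]
            assert label == (1 if score > 0 else 0)


@pytest.fixture()
def small_planted():
    matrix, y, _ = generate_planted_dataset(SyntheticSpec(
        n_samples=120, n_binary=20, n_continuous=20, n_informative=16, seed=2))
    return matrix, y


class TestTraining:
    def test_separable_data_all_slots_valid(self, small_planted):
        matrix, y = small_planted
        rng = np.random.default_rng(0)
        subsets = rng.integers(0, matrix.n_features, size=(3, 12))
        clf = RotationBoostClassifier(
            subsets=subsets, column_kinds=list(matrix.column_kinds),
            random_state=0).fit(matrix.values, y)
        assert 0 < len(clf.slots_) <= 3
        assert all(0 < s.epsilon < 0.5 for s in clf.slots_)
        assert f1_score(y, clf.predict(matrix.values)) >= 0.9

    def test_memorizing_learner_degrades_to_fallback(self, small_planted):
        # 1-NN memorizes its bootstrap; repeated rows make eps ~ 0 -> guard
        matrix, y = small_planted
        clf = RotationBoostClassifier(
            subsets=[[0, 1, 2, 20, 21]], column_kinds=list(matrix.column_kinds),
            base_estimator=KNeighborsClassifier(n_neighbors=1),
            max_retries=2, random_state=0).fit(matrix.values, y)
        if not clf.slots_:  # guard fired on every retry
            pred = clf.predict(matrix.values[:5])
            assert (pred == clf.fallback_label_).all()

    def test_slot_count_bounded_by_k(self, small_planted):
        matrix, y = small_planted
        rng = np.random.default_rng(1)
        subsets = rng.integers(0, matrix.n_features, size=(5, 8))
        clf = RotationBoostClassifier(
            subsets=subsets, column_kinds=list(matrix.column_kinds),
            random_state=1).fit(matrix.values, y)
        assert len(clf.slots_) <= 5

    def test_reproducible_given_seed(self, small_planted):
        matrix, y = small_planted
        subsets = np.random.default_rng(2).integers(
            0, matrix.n_features, size=(3, 10))
        def run():
            return RotationBoostClassifier(
                subsets=subsets, column_kinds=list(matrix.column_kinds),
                random_state=42).fit(matrix.values, y)
        a, b = run(), run()
        np.testing.assert_array_equal(a.predict(matrix.values),
                                      b.predict(matrix.values))
        np.testing.assert_allclose(a.decision_function(matrix.values),
                                   b.decision_function(matrix.values))
        assert [s.beta for s in a.slots_] == [s.beta for s in b.slots_]
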