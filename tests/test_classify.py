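"""rLLR training, prediction, cross-validation and the chance threshold."""

import numpy as np
import pytest
import scipy.stats

import erdmonitor as em
from erdmonitor.classify import penalized_nll_grad, train_rllr
from erdmonitor.containers import MOVEMENT, NO_MOVEMENT


def gaussian_problem(n=120, d=6, sep=2.0, seed=0, blocks=4):
    """Synthetic two-class Gaussian features with block/sequence structure."""
    rng = np.random.default_rng(seed)
    y = rng.permutation(np.repeat([0, 1], n // 2))
    X = rng.standard_normal((n, d))
    X[:, 0] += sep * y
    block = 1 + (np.arange(n) * blocks) // n
    sequence = np.arange(n) // 3
    return X, y, block, sequence


class TestTrain:
    def test_separable_data_perfectly_classified(self):
        X = np.array([[-3.0], [-2.0], [-1.5], [1.5], [2.0], [3.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        model = train_rllr(X, y, lam=1e-6)
        assert np.array_equal(em.predict(model, X), y)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 4))
        y = (rng.random(30) > 0.5).astype(int)
        wb = rng.standard_normal(5)
        lam = 0.7
        nll, grad = penalized_nll_grad(wb, X, y, lam)
        eps = 1e-6
        for i in range(5):
            e = np.zeros(5)
            e[i] = eps
            num = (penalized_nll_grad(wb + e, X, y, lam)[0]
                   - penalized_nll_grad(wb - e, X, y, lam)[0]) / (2 * eps)
            assert num == pytest.approx(grad[i], rel=1e-5, abs=1e-7)

    def test_huge_lambda_shrinks_weights_to_prior(self):
        X, y, _, _ = gaussian_problem(seed=2)
        model = train_rllr(X, y, lam=1e9)
        assert np.linalg.norm(model.w) < 1e-3
        p = em.predict_proba(model, X)
        assert np.allclose(p, y.mean(), atol=1e-3)

    def test_multistart_convexity(self):
        """Different Newton starting points reach the same optimum."""
        X, y, _, _ = gaussian_problem(seed=3)
        rng = np.random.default_rng(4)
        ref = train_rllr(X, y, lam=1.0)
        for _ in range(3):
            init = rng.standard_normal(X.shape[1] + 1) * 5
            alt = train_rllr(X, y, lam=1.0, init=init)
            assert np.allclose(alt.w, ref.w, atol=1e-6)
            assert alt.b == pytest.approx(ref.b, abs=1e-6)

    def test_matches_sklearn_reference(self):
        """Independent check against scikit-learn's penalized logistic fit."""
        sklearn = pytest.importorskip("sklearn.linear_model")
        X, y, _, _ = gaussian_problem(seed=5)
        lam = 2.0
        model = train_rllr(X, y, lam=lam, standardize=False)
        clf = sklearn.LogisticRegression(
            C=1.0 / lam, solver="lbfgs", tol=1e-10, max_iter=5000
        ).fit(X, y)
        assert np.allclose(model.w, clf.coef_[0], atol=1e-4)
        assert model.b == pytest.approx(clf.intercept_[0], abs=1e-4)

    def test_nonfinite_features_rejected(self):
        X = np.array([[1.0], [np.nan]])
        with pytest.raises(ValueError, match="non-finite"):
            train_rllr(X, np.array([0, 1]))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="each class"):
            train_rllr(np.ones((4, 1)), np.zeros(4))


class TestPredict:
    def test_zero_decision_value_gives_half(self):
        model = em.RLLRModel(np.array([1.0, -1.0]), 0.0, 1.0,
                             np.zeros(2), np.ones(2), trained=True)
        assert em.predict_proba(model, np.array([1.0, 1.0]))[0] == pytest.approx(0.5)

    def test_worked_two_feature_example(self):
        """w=(1,−1), b=0, x=(2,1): P = 1/(1+e^(−1)) ≈ 0.7311."""
        model = em.RLLRModel(np.array([1.0, -1.0]), 0.0, 1.0,
                             np.zeros(2), np.ones(2), trained=True)
        p = em.predict_proba(model, np.array([2.0, 1.0]))[0]
        assert p == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-12)

    def test_class_probabilities_sum_to_one(self):
        model = em.RLLRModel(np.array([0.7]), -0.2, 1.0,
                             np.zeros(1), np.ones(1), trained=True)
        x = np.array([[3.0], [-1.0]])
        p = em.predict_proba(model, x)
        # complementary class probability is the logistic of the negated score
        p_other = 1 / (1 + np.exp(((x - 0) / 1) @ model.w + model.b))
        assert np.allclose(p + p_other, 1.0)

    def test_dimension_mismatch_errors(self):
        model = em.RLLRModel(np.ones(3), 0.0, 1.0, np.zeros(3), np.ones(3), trained=True)
        with pytest.raises(ValueError, match="features"):
            em.predict_proba(model, np.ones((2, 2)))

    def test_model_json_round_trip(self):
        X, y, _, _ = gaussian_problem(seed=8)
        model = train_rllr(X, y)
        clone = em.RLLRModel.from_dict(model.to_dict())
        assert np.allclose(em.predict_proba(clone, X), em.predict_proba(model, X))


class TestCrossValidation:
    def test_folds_disjoint_exhaustive_and_balanced(self):
        X, y, _, seq = gaussian_problem(n=100, seed=6)
        res = em.crossvalidate(X, y, k=10, seed=0, unit="trial")
        assert res.n_test == 100
        sizes = [round(r * 10) for r in res.per_split.values()]  # 10 per fold
        assert len(res.per_split) == 10

    def test_fold_sizes_differ_by_at_most_one_trial(self):
        X, y, _, _ = gaussian_problem(n=94, seed=7)
        # reach into the fold builder to inspect sizes directly
        from erdmonitor.classify import _grouped_stratified_folds
        folds = _grouped_stratified_folds(y, np.arange(94), 10, np.random.default_rng(0))
        sizes = sorted(len(f) for f in folds)
        assert sizes[-1] - sizes[0] <= 1
        assert sum(sizes) == 94

    def test_sequence_unit_keeps_sequences_together(self):
        X, y, _, seq = gaussian_problem(n=96, seed=9)
        seq = np.arange(96) // 6
        y = (seq % 2).astype(int)  # condition constant within sequence
        from erdmonitor.classify import _grouped_stratified_folds
        folds = _grouped_stratified_folds(y, seq, 8, np.random.default_rng(1))
        for f in folds:
            for s in np.unique(seq[f]):
                assert np.isin(np.nonzero(seq == s)[0], f).all()

    def test_k_larger_than_n_errors(self):
        X, y, _, _ = gaussian_problem(n=20, seed=10)
        with pytest.raises(ValueError, match="exceeds"):
            em.crossvalidate(X, y, k=30, unit="trial")

    def test_informative_features_classified_above_chance(self):
        X, y, _, seq = gaussian_problem(n=120, sep=3.0, seed=11)
        res = em.crossvalidate(X, y, k=10, seed=0, unit="trial")
        assert res.rate > em.chance_threshold(res.n_test)

    def test_label_permutation_stays_at_chance(self):
        """No-leakage: permuted labels show no systematic above-chance
        classification (cross-validated predictions are dependent, so the
        check is on the permutation distribution, not per-run intervals)."""
        X, y, _, _ = gaussian_problem(n=80, sep=2.5, seed=12)
        rng = np.random.default_rng(13)
        rates = np.array([
            em.crossvalidate(X, rng.permutation(y), k=8, seed=1, unit="trial").rate
            for _ in range(20)
        ])
        t, p = scipy.stats.ttest_1samp(rates, 0.5)
        assert p > 0.01  # mean permutation rate consistent with chance
        true_rate = em.crossvalidate(X, y, k=8, seed=1, unit="trial").rate
        assert true_rate > rates.max()  # real structure dominates every null draw


class TestBlockCalibration:
    def test_matches_crossvalidation_when_blocks_identical(self):
        X, y, block, _ = gaussian_problem(n=160, sep=2.5, seed=14)
        cal = em.block_calibration_eval(X, y, blocks=block)
        cv = em.crossvalidate(X, y, k=10, seed=2, unit="trial")
        assert abs(cal.rate - cv.rate) < 2 * np.sqrt(
            cv.rate * (1 - cv.rate) / cal.n_test + cv.rate * (1 - cv.rate) / cv.n_test
        ) + 0.05

    def test_reports_per_block_rates(self):
        X, y, block, _ = gaussian_problem(n=120, seed=15)
        cal = em.block_calibration_eval(X, y, blocks=block, train_block=1)
        assert set(cal.per_split) == {2, 3, 4}
        assert cal.n_test == (block != 1).sum()

    def test_invalid_train_block_errors(self):
        X, y, block, _ = gaussian_problem(seed=16)
        with pytest.raises(ValueError, match="not present"):
            em.block_calibration_eval(X, y, blocks=block, train_block=9)

    def test_single_block_errors(self):
        X, y, _, _ = gaussian_problem(seed=17)
        with pytest.raises(ValueError, match="2 blocks"):
            em.block_calibration_eval(X, y, blocks=np.ones(len(y)))

    def test_class_missing_from_training_block_errors(self):
        X, y, block, _ = gaussian_problem(seed=18)
        y2 = y.copy()
        y2[block == 1] = 0
        with pytest.raises(ValueError, match="both classes"):
            em.block_calibration_eval(X, y2, blocks=block)


def exact_tail_threshold(n, p0, alpha):
    """Enumeration oracle: smallest c with sum_{i>=c} C(n,i) p0^i (1-p0)^(n-i) <= alpha."""
    from math import comb
    for c in range(n + 1):
        tail = sum(comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(c, n + 1))
        if tail <= alpha:
            return c / n
    return float("nan")


class TestChanceThreshold:
    @pytest.mark.parametrize("n", [10, 36, 100, 288])
    def test_matches_exact_tail_enumeration(self, n):
        assert em.chance_threshold(n) == pytest.approx(exact_tail_threshold(n, 0.5, 0.01))

    def test_hundred_trials_threshold(self):
        # exact tails: P(X>=62)=0.0105 > 0.01, P(X>=63)=0.0060 <= 0.01
        assert em.chance_threshold(100) == pytest.approx(0.63)

    def test_tiny_n_unattainable(self):
        assert np.isnan(em.chance_threshold(1))

    def test_monotone_decreasing_in_n(self):
        vals = [em.chance_threshold(n) for n in (20, 50, 100, 200, 400)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
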