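"""Ensemble combiners: AdaBoost arithmetic, gradient boosting, bagging,
voting, stacking, and Bayesian model averaging."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chdrisk.ensemble import (
    adaboost_round,
    average_probs,
    fit_adaboost,
    fit_bagging,
    fit_bma,
    fit_gradient_boost,
    fit_stacking,
    majority_vote,
    VotingModel,
)
from chdrisk.learners import fit_cart, predict_tree
from chdrisk.resample import SplitSpec, split

from conftest import toy_cohort


class _ConstantModel:
    def __init__(self, p):
        self.p = p

    def predict_proba(self, X):
        return np.full(len(np.atleast_2d(X)), self.p)


class TestAdaboost:
    def _weighted_data(self, seed=0, n=100):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 3))
        y_pm = np.where(X[:, 0] > 0, 1.0, -1.0)
        return X, y_pm

    def test_error_half_gives_zero_alpha(self):
        # eps = 0.5 => alpha = 0.5 ln(1) = 0 by the update formula
        assert 0.5 * math.log((1 - 0.5) / 0.5) == 0.0

    def test_alpha_arithmetic_at_eps_point_one(self):
        X, y_pm = self._weighted_data()
        flip = np.zeros(100, dtype=bool)
        flip[:10] = True
        y_noisy = np.where(flip, -y_pm, y_pm)
        # stump recovers the clean rule -> eps == 0.1 exactly
        w = np.full(100, 0.01)
        _, eps, alpha, _ = adaboost_round(X, y_noisy, w)
        assert eps == pytest.approx(0.1, abs=1e-12)
        assert alpha == pytest.approx(0.5 * math.log(9), abs=1e-9)

    def test_misclassified_weights_strictly_increase(self):
        X, y_pm = self._weighted_data(seed=3)
        y_noisy = y_pm.copy()
        y_noisy[:7] = -y_noisy[:7]
        w = np.full(100, 0.01)
        h, eps, alpha, w_next = adaboost_round(X, y_noisy, w)
        assert alpha > 0
        pred = 2.0 * (predict_tree(h, X) >= 0.5) - 1
        miss = pred != y_noisy
        assert (w_next[miss] > w[miss]).all()
        assert (w_next[~miss] < w[~miss]).all()
        assert w_next.sum() == pytest.approx(1.0, abs=1e-12)

    def test_exponential_loss_bound_decreases(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(150, 4))
        y = ((X[:, 0] + 0.6 * X[:, 1] + 0.3 * rng.normal(size=150)) > 0).astype(int)
        model = fit_adaboost(toy_cohort(X, y), rounds=15, seed=1)
        bound = np.cumprod([2 * math.sqrt(e * (1 - e)) for e in model.errors])
        assert (np.diff(bound) < 0).all()
        # training error is bounded by the exponential-loss bound
        err = (model.predict(X) != y).mean()
        assert err <= bound[-1] + 1e-12


class TestGradientBoost:
    def test_first_round_prediction_is_prior_log_odds(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(100, 2))
        y = (rng.random(100) < 0.3).astype(int)
        m = fit_gradient_boost(toy_cohort(X, y), rounds=1, learning_rate=0.0)
        prior = math.log(y.mean() / (1 - y.mean()))
        np.testing.assert_allclose(m.score(X[:3]), prior, atol=1e-12)

    def test_training_logistic_loss_nonincreasing(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(300, 4))
        y = ((X[:, 0] - X[:, 1]) > 0).astype(int)
        m = fit_gradient_boost(toy_cohort(X, y), loss="logistic", rounds=50)
        F = np.full(len(y), m.f0)
        losses = []
        for t in m.trees:
            F += m.learning_rate * predict_tree(t, X)
            p = np.clip(1 / (1 + np.exp(-F)), 1e-12, 1 - 1e-12)
            losses.append(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())
        assert (np.diff(losses) <= 1e-12).all()

    def test_unit_rate_deep_tree_interpolates_training_data(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(80, 3))
        y = (rng.random(80) < 0.5).astype(int)
        m = fit_gradient_boost(toy_cohort(X, y), loss="logistic",
                               rounds=30, learning_rate=1.0, depth=30)
        assert (m.predict(X) == y).mean() == 1.0


class TestBaggingVoting:
    def test_single_bag_equals_base_on_its_bootstrap(self, tiny_cohort):
        model = fit_bagging(tiny_cohort, lambda c: fit_cart(c), n_bags=1, seed=3)
        idx = model.bootstrap_indices[0]
        direct = fit_cart(tiny_cohort.take_rows(idx))
        X = tiny_cohort.features[:30]
        np.testing.assert_allclose(model.members[0].predict_proba(X),
                                   direct.predict_proba(X), atol=1e-12)

    def test_unanimous_members_give_certain_vote(self):
        model_members = [_ConstantModel(0.9)] * 3
        from chdrisk.ensemble import BaggedModel

        m = BaggedModel(model_members)
        np.testing.assert_allclose(m.predict_proba(np.zeros((4, 2))), 1.0)

    def test_bootstrap_unique_fraction(self):
        rng = np.random.default_rng(8)
        c = toy_cohort(rng.normal(size=(5000, 2)), (rng.random(5000) < 0.5).astype(int))
        model = fit_bagging(c, lambda co: _ConstantModel(0.5), n_bags=3, seed=9)
        for idx in model.bootstrap_indices:
            frac = len(np.unique(idx)) / 5000
            assert frac == pytest.approx(1 - math.exp(-1), abs=0.03)

    @pytest.mark.parametrize("votes,probs,expected", [
        ([1, 1, 0], [0.9, 0.8, 0.1], 1),
        ([0, 0, 1], [0.1, 0.2, 0.9], 0),
        ([1, 0], [0.9, 0.3], 1),      # tie -> mean prob 0.6 > 0.5
        ([1, 0], [0.7, 0.3], 1),      # exact residual tie -> positive class
    ])
    def test_majority_vote_rules(self, votes, probs, expected):
        assert majority_vote(votes, probs) == expected

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 9))
    def test_vote_matches_brute_force_mode(self, seed, m):
        rng = np.random.default_rng(seed)
        p = rng.random(m)
        votes = (p >= 0.5).astype(int)
        got = majority_vote(votes, p)
        pos, neg = votes.sum(), m - votes.sum()
        if pos != neg:
            assert got == int(pos > neg)
        else:
            assert got == (int(p.mean() > 0.5) if p.mean() != 0.5 else 1)

    def test_average_probs(self):
        assert average_probs([0.3, 0.3, 0.3]) == pytest.approx(0.3)
        assert average_probs([0.0, 1.0]) == 0.5
        with pytest.raises(ValueError):
            average_probs([1.5])

    def test_voting_model_permutation_invariant(self, rng):
        members = [_ConstantModel(p) for p in (0.2, 0.7, 0.9)]
        X = np.zeros((5, 2))
        a = VotingModel(members).predict_proba(X)
        b = VotingModel(members[::-1]).predict_proba(X)
        np.testing.assert_allclose(a, b)


class _OracleModel:
    """Predicts the validation labels perfectly (testing construction)."""

    def __init__(self, lookup):
        self.lookup = lookup

    def predict_proba(self, X):
        X = np.atleast_2d(X)
        return np.array([self.lookup.get(tuple(row), 0.5) for row in X])


class TestStacking:
    def _setup(self, seed=0, n=300):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 3))
        y = (X[:, 0] > 0).astype(int)
        val = toy_cohort(X, y)
        lookup = {tuple(row): float(lbl) for row, lbl in zip(X, y)}
        perfect = _OracleModel(lookup)
        noise = [_ConstantModel(0.5), _ConstantModel(0.51)]
        return val, perfect, noise

    def test_meta_weight_largest_on_perfect_base(self):
        val, perfect, noise = self._setup()
        model = fit_stacking([noise[0], perfect, noise[1]], val)
        weights = model.meta.coef[1:]
        assert np.argmax(weights) == 1

    def test_meta_feature_column_count(self):
        val, perfect, noise = self._setup()
        model = fit_stacking([perfect] + noise, val)
        assert model.Z_val.shape == (val.n, 3)

    def test_fewer_than_two_bases_rejected(self):
        val, perfect, _ = self._setup()
        with pytest.raises(ValueError):
            fit_stacking([perfect], val)

    def test_meta_features_only_from_validation_rows(self):
        """Leakage guard: stacking must query base learners only on the
        hold-out rows handed to it."""
        val, perfect, noise = self._setup()
        seen = []

        class Recorder:
            def predict_proba(self, X):
                seen.append(np.atleast_2d(X))
                return np.full(len(np.atleast_2d(X)), 0.5)

        fit_stacking([Recorder(), perfect], val)
        queried = np.vstack(seen)
        val_rows = set(map(tuple, val.features))
        assert all(tuple(r) in val_rows for r in queried)


class TestBma:
    def test_identical_candidates_uniform_and_order_invariant(self, tiny_cohort):
        cands = [_ConstantModel(0.3), _ConstantModel(0.3), _ConstantModel(0.3)]
        m = fit_bma(cands, tiny_cohort)
        np.testing.assert_allclose(m.posterior, 1 / 3, atol=1e-12)
        assert m.posterior.sum() == pytest.approx(1.0, abs=1e-12)

    def test_posterior_order_invariance(self, tiny_cohort):
        cands = [_ConstantModel(p) for p in (0.1, 0.2, 0.4)]
        a = fit_bma(cands, tiny_cohort).posterior
        b = fit_bma(cands[::-1], tiny_cohort).posterior
        np.testing.assert_allclose(a, b[::-1], atol=1e-12)

    def test_log_likelihood_gap_ln4_gives_4_to_1_weights(self):
        y = np.array([1, 0] * 10)
        X = np.zeros((20, 2))
        val = toy_cohort(X, y)

        class Fixed:
            def __init__(self, ll):
                self.ll = ll

            def predict_proba(self, Xq):
                # constant p chosen so total validation log-lik equals ll
                p = math.exp(self.ll / 20)
                # p applies to the true class on every row
                return np.where(y == 1, p, 1 - p)

        m = fit_bma([Fixed(-10.0), Fixed(-10.0 - math.log(4))], val)
        assert m.posterior[0] / m.posterior[1] == pytest.approx(4.0, rel=1e-9)

    def test_zero_probability_candidate_floored_not_inf(self, tiny_cohort):
        cands = [_ConstantModel(0.0), _ConstantModel(0.5)]
        m = fit_bma(cands, tiny_cohort)
        assert np.isfinite(m.log_evidence).all()
        assert m.posterior.sum() == pytest.approx(1.0, abs=1e-12)

    def test_prediction_is_posterior_mixture(self, tiny_cohort):
        cands = [_ConstantModel(0.2), _ConstantModel(0.8)]
        m = fit_bma(cands, tiny_cohort)
        X = np.zeros((4, 2))
        expected = m.posterior[0] * 0.2 + m.posterior[1] * 0.8
        np.testing.assert_allclose(m.predict_proba(X), expected, atol=1e-12)
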