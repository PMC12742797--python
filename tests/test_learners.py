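"""Enhanced learners: soft-gate trees, weighted forests, Huber boosting, and
the SMO-solved SVM."""

import math

import numpy as np
import pytest

from chdrisk.learners import (
    EsvmModel,
    HuberSpec,
    SmoteParams,
    SoftTree,
    SoftTreeParams,
    TreeNode,
    dual_objective,
    esvm_decision,
    fit_anrdt,
    fit_boost,
    fit_cart,
    fit_esvm,
    fit_hirf,
    fit_pgbm,
    fit_svm_baseline,
    grow_tree,
    huber_loss,
    predict_tree,
    rbf_kernel,
    smo_solve,
    soft_gate,
    tree_vote_weights,
)
from chdrisk.resample import SplitSpec, split
from chdrisk.simulate import CohortSpec, generate

from conftest import toy_cohort


class TestSoftGate:
    def test_threshold_point_is_half(self):
        assert soft_gate(2.0, 2.0, 1.0) == pytest.approx(0.5)

    def test_infinite_steepness_is_hard_indicator(self):
        assert soft_gate(3.0, 2.0, math.inf) == 0.0
        assert soft_gate(1.0, 2.0, math.inf) == 1.0
        assert soft_gate(2.0, 2.0, math.inf) == 1.0  # boundary routes left

    def test_unit_steepness_at_log3(self):
        assert soft_gate(math.log(3), 0.0, 1.0) == pytest.approx(0.25)

    def test_overflow_safe(self):
        assert soft_gate(1e6, 0.0, 100.0) == pytest.approx(0.0)
        with pytest.raises(ValueError):
            soft_gate(0.0, 0.0, -1.0)


class TestAnrdt:
    def test_infinite_beta_matches_hard_cart(self, small_cohort):
        tr, va, te = split(small_cohort, SplitSpec(seed=2))
        sub = tr.take_rows(np.arange(200))
        soft = fit_anrdt(sub, va, SoftTreeParams(beta0=math.inf, prune=False))
        hard = fit_cart(sub)
        np.testing.assert_array_equal(soft.predict(te.features),
                                      hard.predict(te.features))

    def test_pure_single_split_dataset(self):
        X = np.array([[0.0], [0.1], [0.2], [0.8], [0.9], [1.0]] * 4)
        y = (X[:, 0] > 0.5).astype(int)
        c = toy_cohort(X, y)
        tree = fit_anrdt(c, c, SoftTreeParams(beta0=50.0))
        assert tree.root.depth() == 1
        assert (tree.predict(X) == y).all()

    def test_path_probabilities_normalise(self, small_cohort):
        tr, va, _ = split(small_cohort, SplitSpec(seed=2))
        tree = fit_anrdt(tr.take_rows(np.arange(300)), va, SoftTreeParams())
        X = va.features[:50]
        p = tree.predict_proba(X)
        assert ((p >= 0) & (p <= 1)).all()
        # complementary-leaf normalisation: swap leaf values to all-ones
        ones = _clone_with_unit_leaves(tree)
        np.testing.assert_allclose(ones.predict_proba(X), 1.0, atol=1e-10)

    def test_predict_matches_explicit_path_enumeration(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(300, 4))
        y = ((X[:, 0] + X[:, 1] * X[:, 2]) > 0).astype(int)
        c = toy_cohort(X, y)
        tree = fit_anrdt(c, c, SoftTreeParams(max_depth=3, prune=False))
        x = rng.normal(size=4)

        def enumerate_paths(node, prob):
            if node.is_leaf:
                return prob * node.value[1]
            g = soft_gate(x[node.feature], node.theta, node.beta)
            return enumerate_paths(node.left, prob * g) + enumerate_paths(
                node.right, prob * (1 - g))

        assert tree.predict_proba(x[None, :])[0] == pytest.approx(
            enumerate_paths(tree.root, 1.0), abs=1e-12)

    def test_noise_robustness_vs_hard_cart(self):
        """With 10% label noise the soft tree's held-out log-loss should beat
        the hard tree's in a clear majority of replicates."""
        wins = 0
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            X = rng.normal(size=(400, 5))
            y = (X[:, 0] + 0.5 * X[:, 1] > 0).astype(int)
            flip = rng.random(400) < 0.10
            y_noisy = np.where(flip, 1 - y, y)
            c = toy_cohort(X[:200], y_noisy[:200])
            v = toy_cohort(X[200:300], y_noisy[200:300])
            Xt, yt = X[300:], y[300:]
            soft = fit_anrdt(c, v, SoftTreeParams())
            hard = fit_cart(c)

            def ll(p):
                p = np.clip(p, 1e-12, 1 - 1e-12)
                return -(yt * np.log(p) + (1 - yt) * np.log(1 - p)).mean()

            if ll(soft.predict_proba(Xt)) <= ll(hard.predict_proba(Xt)):
                wins += 1
        assert wins >= 7

    def test_single_class_train_rejected(self):
        c = toy_cohort(np.random.default_rng(0).normal(size=(30, 2)), [1] * 30)
        with pytest.raises(ValueError):
            fit_anrdt(c, c, SoftTreeParams())


def _clone_with_unit_leaves(tree: SoftTree) -> SoftTree:
    import copy

    clone = copy.deepcopy(tree)

    def walk(node):
        if node.is_leaf:
            node.value = np.array([0.0, 1.0])
            return
        walk(node.left)
        walk(node.right)

    walk(clone.root)
    return clone


class TestHirf:
    def test_weights_normalised_and_identical_trees_uniform(self, rng):
        probs = np.tile(rng.random(30), (5, 1))
        y = (rng.random(30) < 0.5).astype(int)
        w = tree_vote_weights(probs, y)
        assert w == pytest.approx(np.full(5, 0.2), abs=1e-10)
        assert w.sum() == pytest.approx(1.0, abs=1e-10)

    def test_random_tree_gets_smallest_weight(self, rng):
        y = (rng.random(200) < 0.5).astype(int)
        perfect = y.astype(float)
        noisy = rng.random(200)
        probs = np.stack([perfect, perfect, noisy])
        w = tree_vote_weights(probs, y)
        assert w[2] < w[0] and w[2] < w[1]

    def test_weight_permutation_equivariance(self, rng):
        probs = rng.random((6, 40))
        y = (rng.random(40) < 0.4).astype(int)
        w = tree_vote_weights(probs, y)
        perm = rng.permutation(6)
        w_perm = tree_vote_weights(probs[perm], y)
        np.testing.assert_allclose(w_perm, w[perm], atol=1e-12)

    def test_fitted_model_weighted_average(self, small_cohort):
        tr, va, _ = split(small_cohort, SplitSpec(seed=1))
        model = fit_hirf(tr.take_rows(np.arange(400)), va, n_trees=5,
                         smote=SmoteParams(3, 1.0, 0), seed=0)
        assert model.weights.sum() == pytest.approx(1.0, abs=1e-10)
        X = va.features[:20]
        manual = model.weights @ np.stack([predict_tree(t, X) for t in model.trees])
        np.testing.assert_allclose(model.predict_proba(X), manual, atol=1e-12)

    def test_degenerate_weight_vectors(self):
        trees = [TreeNode(value=np.array([0.3, 0.7])), TreeNode(value=np.array([0.9, 0.1]))]
        from chdrisk.learners import HirfModel

        m1 = HirfModel(trees, np.array([1.0, 0.0]))
        x = np.zeros((3, 2))
        np.testing.assert_allclose(m1.predict_proba(x), 0.7)
        m2 = HirfModel(trees, np.array([0.5, 0.5]))
        np.testing.assert_allclose(m2.predict_proba(x), 0.4)


class TestHuberBoost:
    @pytest.mark.parametrize(
        "y,yh,delta,expected",
        [(1.0, 1.0, 1.0, 0.0), (2.0, 0.0, 1.0, 1.5), (3.0, 0.0, 10.0, 4.5)],
    )
    def test_huber_values(self, y, yh, delta, expected):
        assert huber_loss(y, yh, delta) == pytest.approx(expected)

    def test_huber_limit_and_gradient_bound(self):
        r = np.linspace(-5, 5, 101)
        big = huber_loss(r, 0.0, 1e6)
        np.testing.assert_allclose(big, 0.5 * r * r, rtol=1e-9)
        grad = np.gradient(huber_loss(r, 0.0, 1.0), r)
        assert np.abs(grad).max() <= 1.0 + 0.06  # numerical slack

    def test_huber_convex_in_prediction(self):
        yh = np.linspace(-4, 4, 201)
        L = huber_loss(1.0, yh, 1.0)
        assert (np.diff(L, 2) >= -1e-12).all()

    def test_separable_data_fit_within_50_rounds(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 2))
        y = (X[:, 0] > 0).astype(int)
        c = toy_cohort(X, y)
        m = fit_pgbm(c, c, HuberSpec(max_rounds=50, patience=50))
        assert (m.predict(X) == y).mean() == 1.0

    def test_patience_one_on_noise_stops_early(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 3))
        y = (rng.random(200) < 0.5).astype(int)
        c = toy_cohort(X[:100], y[:100])
        v = toy_cohort(X[100:], y[100:])
        m = fit_pgbm(c, v, HuberSpec(max_rounds=100, patience=1))
        assert m.rounds_used < 100

    def test_zero_learning_rate_keeps_prior_log_odds(self, tiny_cohort):
        m = fit_boost(tiny_cohort, loss="huber", learning_rate=0.0, max_rounds=3)
        prior = math.log(tiny_cohort.outcome.mean() / (1 - tiny_cohort.outcome.mean()))
        np.testing.assert_allclose(m.score(tiny_cohort.features[:5]), prior, atol=1e-12)

    def test_retained_round_no_worse_than_final_round(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(300, 4))
        y = (X[:, 0] + rng.normal(0, 2, 300) > 0).astype(int)
        c, v = toy_cohort(X[:200], y[:200]), toy_cohort(X[200:], y[200:])
        m = fit_pgbm(c, v, HuberSpec(max_rounds=80, patience=10))
        assert min(m.val_losses) == pytest.approx(m.val_losses[m.rounds_used - 1], abs=1e-12)


class TestEsvm:
    def _toy(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 3))
        y = (X[:, 0] + 0.5 * X[:, 1] > 0).astype(int)
        return X, y

    def test_dual_feasibility_after_fit(self):
        X, y = self._toy()
        m = fit_svm_baseline((X, y), C=2.0, gamma=0.5)
        assert (m.alpha >= -1e-9).all() and (m.alpha <= 2.0 + 1e-9).all()
        assert abs((m.alpha * m.y_pm).sum()) < 1e-6

    def test_two_separable_points(self):
        X = np.array([[0.0], [2.0]])
        y = np.array([0, 1])
        m = fit_svm_baseline((X, y), C=10.0, gamma=1.0)
        assert m.predict(X).tolist() == [0, 1]
        assert (m.alpha > 0).all()  # both margin points are support vectors

    def test_decision_matches_kernel_sum_arithmetic(self):
        sv = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        alpha = np.array([0.5, 0.3, 0.2])
        y_pm = np.array([1.0, -1.0, -1.0])
        m = EsvmModel(sv, y_pm, alpha, b=0.1, C=1.0, gamma=0.7)
        x = np.array([0.2, 0.3])
        manual = sum(
            a * s * math.exp(-0.7 * ((x - v) ** 2).sum())
            for a, s, v in zip(alpha, y_pm, sv)
        ) + 0.1
        score, label = esvm_decision(m, x)
        assert score == pytest.approx(manual, abs=1e-12)
        assert label == int(manual >= 0)

    def test_score_continuity(self):
        X, y = self._toy()
        m = fit_svm_baseline((X, y), C=1.0, gamma=0.3)
        x = X[0]
        s0, _ = esvm_decision(m, x)
        s1, _ = esvm_decision(m, x + 1e-8)
        assert abs(s1 - s0) < 1e-4

    def test_smo_objective_matches_independent_qp(self):
        """Hand-written SMO vs libsvm on the same dual problem."""
        from sklearn.svm import SVC

        rng = np.random.default_rng(5)
        X = rng.normal(size=(200, 4))
        y = (X[:, 0] + 0.5 * X[:, 1] + 0.3 * rng.normal(size=200) > 0).astype(int)
        y_pm = 2.0 * y - 1
        C, gamma = 1.0, 0.5
        K = rbf_kernel(X, X, gamma)
        alpha, b, _ = smo_solve(K, y_pm, C, seed=1)
        ours = dual_objective(K, y_pm, alpha)
        svc = SVC(C=C, gamma=gamma).fit(X, y)
        ref = np.zeros(len(y))
        ref[svc.support_] = np.abs(svc.dual_coef_[0])
        assert ours == pytest.approx(dual_objective(K, y_pm, ref), abs=1e-2)

    def test_gp_search_returns_within_bounds_and_calibrates(self, small_cohort):
        tr, va, _ = split(small_cohort, SplitSpec(seed=8))
        from chdrisk.cohort import standardize
        from chdrisk.resample import stratified_subsample

        sub = stratified_subsample(standardize(tr), 200, seed=1)
        m = fit_esvm(sub, (standardize(va).features, va.outcome), budget=5, seed=1)
        assert 1e-2 <= m.C <= 1e3 and 1e-4 <= m.gamma <= 10
        p = m.predict_proba(standardize(va).features)
        assert ((p >= 0) & (p <= 1)).all()
        assert len(m.search_history) == 5
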