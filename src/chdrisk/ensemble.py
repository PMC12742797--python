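"""Ensemble combiners: bagging, AdaBoost, gradient boosting, stacking,
majority voting / probability averaging, and Bayesian model averaging.

Every combiner operates over fitted base learners exposing
``predict_proba(X) -> positive-class probability``.  The default "enhanced"
base set is {ANRDT, HIRF, PGBM, ESVM}; the baseline set is the reference
configurations {CART, forest, squared-loss boosting, fixed SVM}.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from ._glm import LogitFit, fit_logistic
from .cohort import Cohort
from .learners import (
    BoostModel,
    TreeNode,
    _as_xy,
    fit_boost,
    grow_tree,
    predict_tree,
)

EPS_MIN = 1e-10   # floor for a zero weighted error when capping alpha


# ===========================================================================
# AdaBoost
# ===========================================================================

@dataclass
class BoostState:
    """Fitted AdaBoost ensemble: stumps h_m with weights alpha_m."""

    learners: list[TreeNode] = field(default_factory=list)
    alphas: list[float] = field(default_factory=list)
    errors: list[float] = field(default_factory=list)

    def score(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        F = np.zeros(len(X))
        for h, a in zip(self.learners, self.alphas):
            F += a * (2.0 * (predict_tree(h, X) >= 0.5) - 1.0)
        return F

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.score(X) >= 0).astype(int)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        # logistic squashing of the additive margin
        return 1.0 / (1.0 + np.exp(-2.0 * np.clip(self.score(X), -250, 250)))


def adaboost_round(
    X: np.ndarray, y_pm: np.ndarray, w: np.ndarray, depth: int = 1, min_leaf: int = 1,
) -> tuple[TreeNode, float, float, np.ndarray]:
    """One boosting round: fit a weighted stump, return (h, eps, alpha, w_next).

    eps is the weighted error, alpha = 1/2 ln((1-eps)/eps); the returned
    sample weights are exponentially reweighted and renormalised.
    """
    if not np.isclose(w.sum(), 1.0):
        raise ValueError("sample weights must sum to 1")
    if (w <= 0).any():
        raise ValueError("sample weights must be positive")
    y01 = ((y_pm + 1) / 2).astype(int)
    h = grow_tree(X, y01, task="clf", sample_weight=w, max_depth=depth, min_leaf=min_leaf)
    pred_pm = 2.0 * (predict_tree(h, X) >= 0.5) - 1.0
    miss = pred_pm != y_pm
    eps = float(w[miss].sum())
    eps_c = min(max(eps, EPS_MIN), 1.0 - EPS_MIN)
    alpha = 0.5 * math.log((1.0 - eps_c) / eps_c)
    w_next = w * np.exp(-alpha * y_pm * pred_pm)
    w_next /= w_next.sum()
    return h, eps, alpha, w_next


def fit_adaboost(
    train: Cohort | tuple, rounds: int = 50, depth: int = 1, seed: int = 2025,
) -> BoostState:
    """AdaBoost with depth-1 stumps.

    A round with weighted error >= 0.5 is re-drawn once from a bootstrap
    resample; if it still fails, boosting stops at that point.
    """
    X, y = _as_xy(train)
    y_pm = 2.0 * y - 1.0
    n = len(y)
    w = np.full(n, 1.0 / n)
    rng = np.random.default_rng(seed)
    state = BoostState()
    for _ in range(rounds):
        h, eps, alpha, w_next = adaboost_round(X, y_pm, w, depth=depth)
        if eps >= 0.5:
            idx = rng.integers(0, n, size=n)
            wb = w[idx] / w[idx].sum()
            h, eps, alpha, _ = adaboost_round(X[idx], y_pm[idx], wb, depth=depth)
            if eps >= 0.5:
                break
            pred_pm = 2.0 * (predict_tree(h, X) >= 0.5) - 1.0
            w_next = w * np.exp(-alpha * y_pm * pred_pm)
            w_next /= w_next.sum()
        state.learners.append(h)
        state.errors.append(eps)
        state.alphas.append(alpha)
        w = w_next
    return state


def fit_gradient_boost(
    train: Cohort | tuple,
    val: Cohort | tuple | None = None,
    loss: str = "logistic",
    learning_rate: float = 0.1,
    rounds: int = 100,
    patience: int | None = None,
    depth: int = 3,
) -> BoostModel:
    """Stagewise gradient boosting (see :func:`chdrisk.learners.fit_boost`);
    the Huber + early-stopping configuration is PGBM."""
    return fit_boost(
        train, val, loss=loss, learning_rate=learning_rate,
        max_rounds=rounds, patience=patience, depth=depth,
    )


# ===========================================================================
# Bagging
# ===========================================================================

@dataclass
class BaggedModel:
    members: list
    bootstrap_indices: list = field(default_factory=list)

    def member_probs(self, X: np.ndarray) -> np.ndarray:
        return np.stack([m.predict_proba(X) for m in self.members])

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        # vote share of the positive class
        votes = (self.member_probs(X) >= 0.5).astype(float)
        return votes.mean(axis=0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        P = self.member_probs(X)
        return np.array([
            majority_vote((P[:, i] >= 0.5).astype(int), P[:, i]) for i in range(P.shape[1])
        ])

    def predict_average(self, X: np.ndarray) -> np.ndarray:
        """Regression hook: plain mean of member outputs."""
        return self.member_probs(X).mean(axis=0)


def fit_bagging(
    train: Cohort,
    base_fit: Callable[[Cohort], object],
    n_bags: int = 25,
    seed: int = 2025,
) -> BaggedModel:
    """Train ``base_fit`` on ``n_bags`` bootstrap resamples; classify by
    majority vote, probability = vote share."""
    if n_bags < 1:
        raise ValueError("n_bags must be >= 1")
    rng = np.random.default_rng(seed)
    members, indices = [], []
    for _ in range(n_bags):
        idx = rng.integers(0, train.n, size=train.n)
        indices.append(idx)
        members.append(base_fit(train.take_rows(idx)))
    return BaggedModel(members, indices)


# ===========================================================================
# Voting / averaging
# ===========================================================================

def majority_vote(labels: Sequence[int], probabilities: Sequence[float]) -> int:
    """Modal class; ties broken by mean probability vs 0.5, residual exact
    tie resolved toward the positive class."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("need at least one learner")
    pos = int((labels == 1).sum())
    neg = labels.size - pos
    if pos != neg:
        return int(pos > neg)
    mean_p = float(np.mean(probabilities))
    if mean_p != 0.5:
        return int(mean_p > 0.5)
    return 1


def average_probs(probabilities: Sequence[float]) -> float:
    p = np.asarray(probabilities, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    return float(p.mean())


@dataclass
class VotingModel:
    members: list

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return np.stack([m.predict_proba(X) for m in self.members]).mean(axis=0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        P = np.stack([m.predict_proba(X) for m in self.members])
        return np.array([
            majority_vote((P[:, i] >= 0.5).astype(int), P[:, i]) for i in range(P.shape[1])
        ])


# ===========================================================================
# Stacking
# ===========================================================================

@dataclass
class StackModel:
    base_learners: list
    meta: LogitFit
    Z_val: np.ndarray

    def meta_features(self, X: np.ndarray) -> np.ndarray:
        return np.column_stack([m.predict_proba(X) for m in self.base_learners])

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Z = self.meta_features(X)
        return self.meta.predict_proba(np.column_stack([np.ones(len(Z)), Z]))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)


def fit_stacking(base_learners: list, val: Cohort | tuple) -> StackModel:
    """Meta-feature matrix Z from base-learner probabilities on the hold-out
    rows; meta-learner = IRLS logistic regression (ridge-stabilised when the
    meta problem separates)."""
    if len(base_learners) < 2:
        raise ValueError("stacking needs at least 2 base learners")
    Xv, yv = _as_xy(val)
    Z = np.column_stack([m.predict_proba(Xv) for m in base_learners])
    meta = fit_logistic(Z, yv, add_intercept=True)
    if meta.ridged:
        warnings.warn("meta-learner separation; ridge-stabilised IRLS used")
    return StackModel(list(base_learners), meta, Z)


# ===========================================================================
# Bayesian model averaging
# ===========================================================================

@dataclass
class BmaModel:
    candidates: list
    posterior: np.ndarray        # p_i, sums to 1
    log_evidence: np.ndarray

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        P = np.stack([m.predict_proba(X) for m in self.candidates])
        return self.posterior @ P

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)


def fit_bma(candidates: list, val: Cohort | tuple,
            priors: Sequence[float] | None = None) -> BmaModel:
    """Posterior model weights from validation likelihood.

    Evidence is approximated by exp(validation log-likelihood) with uniform
    priors by default; weights are normalised through log-sum-exp.
    Candidate probabilities are floored at 1e-12 so an observed label with
    zero predicted mass cannot produce a -inf evidence.
    """
    if not candidates:
        raise ValueError("need at least one candidate model")
    Xv, yv = _as_xy(val)
    if len(yv) == 0:
        raise ValueError("validation set is empty")
    log_ev = np.empty(len(candidates))
    for i, m in enumerate(candidates):
        p = np.clip(m.predict_proba(Xv), 1e-12, 1 - 1e-12)
        log_ev[i] = float(yv @ np.log(p) + (1 - yv) @ np.log(1 - p))
    log_prior = (
        np.log(np.asarray(priors, dtype=float))
        if priors is not None
        else np.zeros(len(candidates))
    )
    log_post = log_ev + log_prior
    log_post -= log_post.max()
    post = np.exp(log_post)
    post /= post.sum()
    return BmaModel(list(candidates), post, log_ev)
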