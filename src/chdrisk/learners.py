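"""Base and enhanced learners.

Four enhanced variants of the classical tree/kernel learners, plus the thin
baseline configurations they are compared against:

* ANRDT  - decision tree whose splits are sigmoid gates
  ``f(x) = 1 / (1 + exp(beta (x - theta)))`` (the left-routing probability;
  ``beta -> inf`` recovers hard "x <= theta goes left" CART), with
  cost-complexity pruning selected on validation log-loss.
* HIRF   - random forest trained on SMOTE-balanced bootstraps, trees combined
  with nonuniform weights ``y_hat = sum_i w_i T_i(x)`` derived from each
  tree's validation-set contribution toward the true class.
* PGBM   - stagewise gradient boosting driven by the Huber loss on margin
  residuals, with patience-based early stopping on validation log-loss.
* ESVM   - RBF-kernel SVM solved in the dual by SMO, with (C, gamma) chosen
  by Gaussian-process expected-improvement search over cross-validated
  accuracy, and Platt-style probability calibration on validation scores.

Baselines (hard CART, uniform-weight forest, squared-loss boosting, fixed
hyperparameter SVM) reuse the same internals.
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from ._glm import LogitFit, fit_logistic
from .cohort import Cohort
from .resample import SmoteParams, kfold, smote_balance

DEFAULT_SEED = 2025


def _as_xy(data: Cohort | tuple[np.ndarray, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, Cohort):
        return data.features, data.outcome
    X, y = data
    return np.asarray(X, dtype=float), np.asarray(y, dtype=int)


# ===========================================================================
# CART internals (shared by every tree-based learner)
# ===========================================================================

@dataclass
class TreeNode:
    """Recursive tree node: internal (feature, theta[, beta]) or leaf value."""

    value: np.ndarray | float = 0.0      # class probs (2,) for clf, mean for reg
    n: int = 0
    r_node: float = 0.0                  # resubstitution error share as a leaf
    feature: int = -1
    theta: float = 0.0
    beta: float | None = None            # soft-gate steepness; None = hard
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.left.depth(), self.right.depth())

    def n_leaves(self) -> int:
        if self.is_leaf:
            return 1
        return self.left.n_leaves() + self.right.n_leaves()


def _best_split(X, target, w, cols, min_leaf, task):
    """Return (gain, feature, theta) of the best impurity-decreasing split."""
    n = len(target)
    best = (0.0, -1, 0.0)
    wsum = w.sum()
    for j in cols:
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        cs, ct, cw = col[order], target[order], w[order]
        # candidate boundaries: between distinct consecutive values
        diff = np.diff(cs) > 0
        if not diff.any():
            continue
        pos = np.flatnonzero(diff) + 1          # split before index pos
        # honour min_leaf on raw counts
        pos = pos[(pos >= min_leaf) & (n - pos >= min_leaf)]
        if pos.size == 0:
            continue
        wl = np.cumsum(cw)[pos - 1]
        wr = wsum - wl
        if task == "clf":
            wy = np.cumsum(cw * ct)[pos - 1]
            p_l = wy / wl
            p_r = (cw @ ct - wy) / wr
            gini_l = 2 * p_l * (1 - p_l)
            gini_r = 2 * p_r * (1 - p_r)
            parent_p = (cw @ ct) / wsum
            parent = 2 * parent_p * (1 - parent_p)
            gain = parent - (wl * gini_l + wr * gini_r) / wsum
        else:
            s = np.cumsum(cw * ct)[pos - 1]
            s2_all, s_all = cw @ (ct * ct), cw @ ct
            sse_l = np.cumsum(cw * ct * ct)[pos - 1] - s * s / wl
            sse_r = (s2_all - np.cumsum(cw * ct * ct)[pos - 1]) - (s_all - s) ** 2 / wr
            parent = s2_all - s_all * s_all / wsum
            gain = (parent - (sse_l + sse_r)) / wsum
        k = int(np.argmax(gain))
        if gain[k] > best[0] + 1e-15:
            theta = 0.5 * (cs[pos[k] - 1] + cs[pos[k]])
            best = (float(gain[k]), j, float(theta))
    return best


def grow_tree(
    X: np.ndarray,
    target: np.ndarray,
    *,
    task: str = "clf",
    sample_weight: np.ndarray | None = None,
    max_depth: int = 6,
    min_leaf: int = 5,
    max_features: int | None = None,
    rng: np.random.Generator | None = None,
) -> TreeNode:
    """Greedy CART: Gini for classification, SSE for regression."""
    X = np.asarray(X, dtype=float)
    target = np.asarray(target, dtype=float)
    w = np.ones(len(target)) if sample_weight is None else np.asarray(sample_weight, float)
    total_w = w.sum()
    d = X.shape[1]

    def leaf_value(t, ww):
        if task == "clf":
            p1 = float(ww @ t / ww.sum())
            return np.array([1 - p1, p1])
        return float(ww @ t / ww.sum())

    def node_error(t, ww):
        # share of total weighted error if this node were a leaf
        if task == "clf":
            p1 = float(ww @ t / ww.sum())
            return ww.sum() / total_w * min(p1, 1 - p1)
        m = float(ww @ t / ww.sum())
        return float(ww @ (t - m) ** 2) / total_w

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        t, ww = target[idx], w[idx]
        node = TreeNode(value=leaf_value(t, ww), n=len(idx), r_node=node_error(t, ww))
        pure = (task == "clf" and (t == t[0]).all()) or (task == "reg" and np.ptp(t) == 0)
        if depth >= max_depth or len(idx) < 2 * min_leaf or pure:
            return node
        if max_features is not None and max_features < d:
            cols = (rng or np.random.default_rng()).choice(d, size=max_features, replace=False)
        else:
            cols = np.arange(d)
        gain, j, theta = _best_split(X[idx], t, ww, cols, min_leaf, task)
        if j < 0:
            return node
        go_left = X[idx, j] <= theta
        node.feature, node.theta = j, theta
        node.left = build(idx[go_left], depth + 1)
        node.right = build(idx[~go_left], depth + 1)
        return node

    return build(np.arange(len(target)), 0)


def predict_tree(node: TreeNode, X: np.ndarray) -> np.ndarray:
    """Hard routing; returns class-1 probability (clf) or value (reg)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out = np.empty(len(X))
    for i, x in enumerate(X):
        t = node
        while not t.is_leaf:
            t = t.left if x[t.feature] <= t.theta else t.right
        out[i] = t.value[1] if isinstance(t.value, np.ndarray) else t.value
    return out


# ---------------------------------------------------------------------------
# Cost-complexity pruning (weakest-link sequence)
# ---------------------------------------------------------------------------

def _subtree_error(node: TreeNode) -> float:
    if node.is_leaf:
        return node.r_node
    return _subtree_error(node.left) + _subtree_error(node.right)


def _internal_nodes(node: TreeNode) -> list[TreeNode]:
    if node.is_leaf:
        return []
    return [node] + _internal_nodes(node.left) + _internal_nodes(node.right)


def pruning_sequence(root: TreeNode) -> list[TreeNode]:
    """Nested subtrees from the full tree down to the root leaf, obtained by
    repeatedly collapsing the weakest link (smallest alpha)."""
    seq = [copy.deepcopy(root)]
    work = copy.deepcopy(root)
    while not work.is_leaf:
        internals = _internal_nodes(work)
        alphas = [
            (t.r_node - _subtree_error(t)) / max(t.n_leaves() - 1, 1) for t in internals
        ]
        a_min = min(alphas)
        for t, a in zip(internals, alphas):
            if a <= a_min + 1e-15:
                t.left = t.right = None
                t.feature = -1
        seq.append(copy.deepcopy(work))
    return seq


# ===========================================================================
# ANRDT: soft-gated decision tree
# ===========================================================================

def soft_gate(x: float | np.ndarray, theta: float, beta: float) -> float | np.ndarray:
    """Left-routing probability 1 / (1 + exp(beta (x - theta))).

    ``beta -> inf`` recovers the hard indicator of ``x <= theta``.
    """
    if beta <= 0:
        raise ValueError("beta must be > 0")
    if math.isinf(beta):
        return (np.asarray(x) <= theta).astype(float)
    z = np.clip(beta * (np.asarray(x, dtype=float) - theta), -500, 500)
    return 1.0 / (1.0 + np.exp(z))


@dataclass
class SoftTreeParams:
    max_depth: int = 6
    min_leaf: int = 5
    beta0: float = 4.0        # per-node steepness = beta0 / sd(split feature)
    prune: bool = True        # cost-complexity pruning against validation log-loss


@dataclass
class SoftTree:
    """Fitted soft decision tree (ANRDT model object)."""

    root: TreeNode
    params: SoftTreeParams
    feature_sd: np.ndarray

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.zeros(len(X))

        def walk(node: TreeNode, path: np.ndarray) -> None:
            nonlocal out
            if node.is_leaf:
                out += path * node.value[1]
                return
            g = soft_gate(X[:, node.feature], node.theta, node.beta)
            walk(node.left, path * g)
            walk(node.right, path * (1.0 - g))

        walk(self.root, np.ones(len(X)))
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)


def _set_betas(node: TreeNode, beta0: float, sd: np.ndarray) -> None:
    if node.is_leaf:
        return
    s = sd[node.feature] if sd[node.feature] > 0 else 1.0
    node.beta = beta0 / s if not math.isinf(beta0) else math.inf
    _set_betas(node.left, beta0, sd)
    _set_betas(node.right, beta0, sd)


def _log_loss(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


def fit_anrdt(
    train: Cohort | tuple,
    val: Cohort | tuple,
    params: SoftTreeParams | None = None,
) -> SoftTree:
    """Grow a hard Gini tree, soften each gate with ``beta0 / sd(feature)``,
    then pick the cost-complexity pruning level minimising validation
    log-loss (ties toward the smaller tree)."""
    params = params or SoftTreeParams()
    X, y = _as_xy(train)
    Xv, yv = _as_xy(val)
    if len(np.unique(y)) < 2:
        raise ValueError("training outcome has a single class")
    sd = X.std(axis=0, ddof=0)
    root = grow_tree(X, y, task="clf", max_depth=params.max_depth, min_leaf=params.min_leaf)
    if not params.prune:
        _set_betas(root, params.beta0, sd)
        return SoftTree(root, params, sd)
    best_tree, best_loss = None, np.inf
    for cand in pruning_sequence(root):
        _set_betas(cand, params.beta0, sd)
        tree = SoftTree(cand, params, sd)
        loss = _log_loss(yv, tree.predict_proba(Xv))
        if loss <= best_loss + 1e-12:          # ties favour the more pruned tree
            best_tree, best_loss = tree, min(loss, best_loss)
    return best_tree


@dataclass
class CartModel:
    """Baseline hard CART (reference configuration of the same internals)."""

    root: TreeNode

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return predict_tree(self.root, X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)


def fit_cart(train: Cohort | tuple, max_depth: int = 6, min_leaf: int = 5) -> CartModel:
    X, y = _as_xy(train)
    return CartModel(grow_tree(X, y, task="clf", max_depth=max_depth, min_leaf=min_leaf))


# ===========================================================================
# HIRF: SMOTE-balanced forest with contribution-weighted trees
# ===========================================================================

@dataclass
class HirfModel:
    trees: list[TreeNode]
    weights: np.ndarray

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        probs = np.stack([predict_tree(t, X) for t in self.trees])
        return self.weights @ probs

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)


def tree_vote_weights(tree_probs: np.ndarray, y_val: np.ndarray) -> np.ndarray:
    """Per-tree contribution scores from validation votes.

    For the tree-averaging game the Shapley contribution of tree ``i`` on a
    validation row reduces to its own signed vote toward the true class,
    ``p_i(true class) - 0.5``.  Scores are the validation means of those
    votes clipped at zero, normalised to sum to one; a uniform fallback
    applies when every score is zero.
    """
    p_true = np.where(y_val[None, :] == 1, tree_probs, 1.0 - tree_probs)
    raw = np.clip(p_true - 0.5, 0.0, None).mean(axis=1)
    if raw.sum() <= 0:
        warnings.warn("all tree contribution scores are zero; using uniform weights")
        return np.full(len(raw), 1.0 / len(raw))
    return raw / raw.sum()


def fit_hirf(
    train: Cohort,
    val: Cohort | tuple,
    n_trees: int = 200,
    smote: SmoteParams | None = None,
    seed: int = DEFAULT_SEED,
    max_depth: int = 10,
    min_leaf: int = 2,
) -> HirfModel:
    """Forest of Gini trees, each on a SMOTE-balanced bootstrap with sqrt(d)
    feature subsampling per split; tree weights from validation votes."""
    smote = smote or SmoteParams()
    rng = np.random.default_rng(seed)
    Xv, yv = _as_xy(val)
    d = train.d
    mtry = max(1, int(round(math.sqrt(d))))
    trees: list[TreeNode] = []
    for _ in range(n_trees):
        idx = rng.integers(0, train.n, size=train.n)
        boot = train.take_rows(idx)
        n_min = int(min((boot.outcome == 1).sum(), (boot.outcome == 0).sum()))
        if n_min > smote.k:
            boot = smote_balance(
                boot,
                SmoteParams(smote.k, smote.target_ratio, seed=int(rng.integers(2**31))),
            )
        trees.append(
            grow_tree(
                boot.features, boot.outcome, task="clf", max_depth=max_depth,
                min_leaf=min_leaf, max_features=mtry, rng=rng,
            )
        )
    if len(np.unique(yv)) < 2:
        warnings.warn("single-class validation set; HIRF weights fall back to uniform")
        w = np.full(n_trees, 1.0 / n_trees)
    else:
        probs = np.stack([predict_tree(t, Xv) for t in trees])
        w = tree_vote_weights(probs, yv)
    return HirfModel(trees, w)


def fit_forest(
    train: Cohort | tuple, n_trees: int = 200, seed: int = DEFAULT_SEED,
    max_depth: int = 10, min_leaf: int = 2,
) -> HirfModel:
    """Baseline uniform-weight bagged forest (no SMOTE, no reweighting)."""
    X, y = _as_xy(train)
    rng = np.random.default_rng(seed)
    d = X.shape[1]
    mtry = max(1, int(round(math.sqrt(d))))
    trees = []
    for _ in range(n_trees):
        idx = rng.integers(0, len(y), size=len(y))
        trees.append(
            grow_tree(X[idx], y[idx], task="clf", max_depth=max_depth,
                      min_leaf=min_leaf, max_features=mtry, rng=rng)
        )
    return HirfModel(trees, np.full(n_trees, 1.0 / n_trees))


# ===========================================================================
# PGBM: Huber-loss gradient boosting with early stopping
# ===========================================================================

def huber_loss(y: float | np.ndarray, y_hat: float | np.ndarray, delta: float = 1.0):
    """Huber loss: quadratic inside |r| <= delta, linear outside."""
    if delta <= 0:
        raise ValueError("delta must be > 0")
    r = np.abs(np.asarray(y, dtype=float) - np.asarray(y_hat, dtype=float))
    out = np.where(r <= delta, 0.5 * r * r, delta * (r - 0.5 * delta))
    return float(out) if out.ndim == 0 else out


@dataclass
class HuberSpec:
    delta: float = 1.0
    patience: int = 10
    learning_rate: float = 0.1
    max_rounds: int = 200

    def __post_init__(self) -> None:
        if self.delta <= 0 or self.patience < 1:
            raise ValueError("delta must be > 0 and patience >= 1")


@dataclass
class BoostModel:
    """Stagewise additive model F(x) on the log-odds scale."""

    f0: float
    trees: list[TreeNode]
    learning_rate: float
    loss: str
    rounds_used: int
    val_losses: list[float] = field(default_factory=list)

    def score(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        F = np.full(len(X), self.f0)
        for t in self.trees:
            F += self.learning_rate * predict_tree(t, X)
        return F

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-np.clip(self.score(X), -500, 500)))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)


def fit_boost(
    train: Cohort | tuple,
    val: Cohort | tuple | None = None,
    loss: str = "logistic",
    learning_rate: float = 0.1,
    max_rounds: int = 200,
    patience: int | None = None,
    depth: int = 3,
    delta: float = 1.0,
    min_leaf: int = 5,
) -> BoostModel:
    """Gradient boosting on the log-odds scale.

    ``logistic``: pseudo-residual y - sigmoid(F).  ``huber``: Huber gradient
    of the margin residual s - tanh(F/2) with labels s in {-1, +1}, i.e. the
    residual clipped at delta - outliers pull with bounded force.  ``ls`` is
    the unclipped squared-loss variant (delta -> inf).  With ``patience``
    set, training stops when validation log-loss has not improved for that
    many rounds and the best round is retained.
    """
    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    X, y = _as_xy(train)
    if len(np.unique(y)) < 2:
        raise ValueError("training outcome has a single class")
    p_bar = y.mean()
    f0 = math.log(p_bar / (1.0 - p_bar))
    F = np.full(len(y), f0)
    s = 2.0 * y - 1.0
    trees: list[TreeNode] = []
    val_losses: list[float] = []
    best_round, best_loss = 0, np.inf
    if val is not None:
        Xv, yv = _as_xy(val)
        Fv = np.full(len(yv), f0)
    for m in range(1, max_rounds + 1):
        p = 1.0 / (1.0 + np.exp(-np.clip(F, -500, 500)))
        if loss == "logistic":
            g = y - p
        elif loss in ("huber", "ls"):
            r = s - np.tanh(F / 2.0)
            g = np.clip(r, -delta, delta) if loss == "huber" else r
        else:
            raise ValueError(f"unknown loss {loss!r}")
        tree = grow_tree(X, g, task="reg", max_depth=depth, min_leaf=min_leaf)
        trees.append(tree)
        F += learning_rate * predict_tree(tree, X)
        if val is not None:
            Fv += learning_rate * predict_tree(tree, Xv)
            pv = 1.0 / (1.0 + np.exp(-np.clip(Fv, -500, 500)))
            vloss = _log_loss(yv, pv)
            val_losses.append(vloss)
            if vloss < best_loss - 1e-12:
                best_loss, best_round = vloss, m
            elif patience is not None and m - best_round >= patience:
                break
    rounds = best_round if (val is not None and patience is not None) else len(trees)
    rounds = rounds or len(trees)
    return BoostModel(f0, trees[:rounds], learning_rate, loss, rounds, val_losses)


def fit_pgbm(
    train: Cohort | tuple,
    val: Cohort | tuple,
    spec: HuberSpec | None = None,
    depth: int = 3,
) -> BoostModel:
    """PGBM = Huber-loss boosting + patience-based early stopping."""
    spec = spec or HuberSpec()
    return fit_boost(
        train, val, loss="huber", learning_rate=spec.learning_rate,
        max_rounds=spec.max_rounds, patience=spec.patience, depth=depth,
        delta=spec.delta,
    )


# ===========================================================================
# ESVM: SMO-solved RBF SVM with GP expected-improvement tuning
# ===========================================================================

SVM_MAX_N = 2000   # dense-kernel SMO solver limit (O(n^2) memory)


def rbf_kernel(A: np.ndarray, B: np.ndarray, gamma: float) -> np.ndarray:
    a2 = (A * A).sum(axis=1)[:, None]
    b2 = (B * B).sum(axis=1)[None, :]
    d2 = np.maximum(a2 + b2 - 2.0 * A @ B.T, 0.0)
    return np.exp(-gamma * d2)


def smo_solve(
    K: np.ndarray, y: np.ndarray, C: float, tol: float = 1e-3,
    max_sweeps: int = 2000, seed: int = 0,
) -> tuple[np.ndarray, float, int]:
    """Platt-style SMO for the dual box-constrained QP.

    Returns (alpha, b, iterations); raises on non-convergence.
    """
    n = len(y)
    rng = np.random.default_rng(seed)
    alpha = np.zeros(n)
    b = 0.0
    # error cache E_i = f(x_i) - y_i with f = (alpha*y) @ K + b
    E = -y.astype(float) + b
    eps = 1e-12
    iterations = 0

    def take_step(i1: int, i2: int) -> bool:
        nonlocal b, E
        if i1 == i2:
            return False
        a1, a2 = alpha[i1], alpha[i2]
        y1, y2 = y[i1], y[i2]
        E1, E2 = E[i1], E[i2]
        s = y1 * y2
        if s > 0:
            L, H = max(0.0, a1 + a2 - C), min(C, a1 + a2)
        else:
            L, H = max(0.0, a2 - a1), min(C, C + a2 - a1)
        if H - L < eps:
            return False
        k11, k12, k22 = K[i1, i1], K[i1, i2], K[i2, i2]
        eta = k11 + k22 - 2.0 * k12
        if eta > eps:
            a2_new = a2 + y2 * (E1 - E2) / eta
            a2_new = min(H, max(L, a2_new))
        else:
            # objective at the ends of the feasible segment
            f1 = y1 * (E1 + b) - a1 * k11 - s * a2 * k12
            f2 = y2 * (E2 + b) - s * a1 * k12 - a2 * k22
            L1 = a1 + s * (a2 - L)
            H1 = a1 + s * (a2 - H)
            obj_L = L1 * f1 + L * f2 + 0.5 * L1 * L1 * k11 + 0.5 * L * L * k22 + s * L * L1 * k12
            obj_H = H1 * f1 + H * f2 + 0.5 * H1 * H1 * k11 + 0.5 * H * H * k22 + s * H * H1 * k12
            if obj_L < obj_H - eps:
                a2_new = L
            elif obj_L > obj_H + eps:
                a2_new = H
            else:
                a2_new = a2
        if abs(a2_new - a2) < eps * (a2_new + a2 + eps):
            return False
        a1_new = a1 + s * (a2 - a2_new)
        # bias update keeping KKT on the two working points
        b1 = b - E1 - y1 * (a1_new - a1) * k11 - y2 * (a2_new - a2) * k12
        b2 = b - E2 - y1 * (a1_new - a1) * k12 - y2 * (a2_new - a2) * k22
        if 0 < a1_new < C:
            b_new = b1
        elif 0 < a2_new < C:
            b_new = b2
        else:
            b_new = 0.5 * (b1 + b2)
        E += (
            y1 * (a1_new - a1) * K[i1]
            + y2 * (a2_new - a2) * K[i2]
            + (b_new - b)
        )
        alpha[i1], alpha[i2] = a1_new, a2_new
        b = b_new
        return True

    def examine(i2: int) -> bool:
        y2, a2, E2 = y[i2], alpha[i2], E[i2]
        r2 = E2 * y2
        if (r2 < -tol and a2 < C) or (r2 > tol and a2 > 0):
            nb = np.flatnonzero((alpha > eps) & (alpha < C - eps))
            if nb.size > 1:
                i1 = int(nb[np.argmax(np.abs(E[nb] - E2))])
                if take_step(i1, i2):
                    return True
            start = int(rng.integers(n))
            for k in range(n):
                i1 = (start + k) % n
                if eps < alpha[i1] < C - eps and take_step(i1, i2):
                    return True
            start = int(rng.integers(n))
            for k in range(n):
                i1 = (start + k) % n
                if take_step(i1, i2):
                    return True
        return False

    examine_all = True
    num_changed = 0
    while num_changed > 0 or examine_all:
        iterations += 1
        if iterations > max_sweeps:
            raise RuntimeError(f"SMO failed to converge after {iterations - 1} sweeps")
        num_changed = 0
        idx = range(n) if examine_all else np.flatnonzero((alpha > eps) & (alpha < C - eps))
        for i2 in idx:
            num_changed += examine(int(i2))
        if examine_all:
            examine_all = False
        elif num_changed == 0:
            examine_all = True
    return alpha, b, iterations


def dual_objective(K: np.ndarray, y: np.ndarray, alpha: np.ndarray) -> float:
    """SVM dual objective: sum(alpha) - 1/2 alpha^T (yy^T o K) alpha."""
    ay = alpha * y
    return float(alpha.sum() - 0.5 * ay @ K @ ay)


@dataclass
class EsvmModel:
    X_train: np.ndarray
    y_pm: np.ndarray            # labels in {-1, +1}
    alpha: np.ndarray
    b: float
    C: float
    gamma: float
    platt: LogitFit | None = None
    search_history: list[tuple[float, float, float]] = field(default_factory=list)

    def decision(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Kx = rbf_kernel(self.X_train, X, self.gamma)
        return (self.alpha * self.y_pm) @ Kx + self.b

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision(X) >= 0).astype(int)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        s = self.decision(X)
        if self.platt is None:
            return 1.0 / (1.0 + np.exp(-np.clip(s, -500, 500)))
        return self.platt.predict_proba(np.column_stack([np.ones(len(s)), s]))


def esvm_decision(model: EsvmModel, x: np.ndarray) -> tuple[float, int]:
    """Signed score and class for one instance (Eq.-form kernel sum)."""
    s = float(model.decision(np.atleast_2d(x))[0])
    return s, int(s >= 0)


def _fit_svm_raw(X, y, C, gamma, seed=0) -> tuple[np.ndarray, float]:
    y_pm = 2.0 * np.asarray(y, dtype=float) - 1.0
    K = rbf_kernel(X, X, gamma)
    alpha, b, _ = smo_solve(K, y_pm, C, seed=seed)
    return alpha, b


# -- Gaussian-process expected improvement over (log10 C, log10 gamma) -----

_BOUNDS = np.array([[-2.0, 3.0], [-4.0, 1.0]])


def _gp_ei_propose(Xobs: np.ndarray, yobs: np.ndarray, rng: np.random.Generator,
                   n_cand: int = 256, length_scale: float = 0.3) -> np.ndarray:
    """Pick the next point in the unit square by expected improvement under a
    fixed-hyperparameter RBF Gaussian process."""
    var = yobs.var() + 1e-8
    d2 = ((Xobs[:, None, :] - Xobs[None, :, :]) ** 2).sum(-1)
    Kmat = var * np.exp(-0.5 * d2 / length_scale**2) + 1e-6 * np.eye(len(Xobs))
    L = np.linalg.cholesky(Kmat)
    mu0 = yobs.mean()
    alpha_gp = np.linalg.solve(L.T, np.linalg.solve(L, yobs - mu0))
    cand = rng.random((n_cand, 2))
    dc = ((cand[:, None, :] - Xobs[None, :, :]) ** 2).sum(-1)
    Kc = var * np.exp(-0.5 * dc / length_scale**2)
    mu = mu0 + Kc @ alpha_gp
    v = np.linalg.solve(L, Kc.T)
    sig = np.sqrt(np.maximum(var - (v * v).sum(0), 1e-12))
    best = yobs.max()
    z = (mu - best) / sig
    ei = (mu - best) * norm.cdf(z) + sig * norm.pdf(z)
    return cand[int(np.argmax(ei))]


def fit_esvm(
    train: Cohort | tuple,
    val: Cohort | tuple | None = None,
    budget: int = 10,
    seed: int = DEFAULT_SEED,
    cv_folds: int = 5,
) -> EsvmModel:
    """RBF SVM with (C, gamma) chosen by GP expected improvement on the
    log10 grid [-2, 3] x [-4, 1], scored by k-fold CV accuracy; final fit on
    the full training set, Platt calibration on validation scores."""
    X, y = _as_xy(train)
    if len(y) > SVM_MAX_N:
        raise ValueError(f"ESVM dense solver limited to n <= {SVM_MAX_N}; subsample first")
    sds = X.std(axis=0, ddof=0)
    non_binary = np.array([len(np.unique(X[:, j])) > 2 for j in range(X.shape[1])])
    if non_binary.any() and (((sds < 0.5) | (sds > 2.0)) & non_binary).any():
        warnings.warn("features look non-standardized (sd outside [0.5, 2])")
    rng = np.random.default_rng(seed)

    folds = []
    for tr, te in kfold(Cohort(
        X, y, [f"f{j}" for j in range(X.shape[1])],
        ["continuous"] * X.shape[1], ["clinical"] * X.shape[1],
    ), folds=cv_folds, seed=seed):
        folds.append(((tr.features, tr.outcome), (te.features, te.outcome)))

    def cv_accuracy(u: np.ndarray) -> float:
        logC, logG = _BOUNDS[:, 0] + u * (_BOUNDS[:, 1] - _BOUNDS[:, 0])
        C, gamma = 10.0**logC, 10.0**logG
        accs = []
        for (Xt, yt), (Xe, ye) in folds:
            try:
                a, b = _fit_svm_raw(Xt, yt, C, gamma, seed=seed)
            except RuntimeError:
                return 0.0
            s = (a * (2 * yt - 1)) @ rbf_kernel(Xt, Xe, gamma) + b
            accs.append(((s >= 0).astype(int) == ye).mean())
        return float(np.mean(accs))

    n_init = min(4, budget)
    Xobs = rng.random((n_init, 2))
    yobs = np.array([cv_accuracy(u) for u in Xobs])
    history = []
    for _ in range(budget - n_init):
        u = _gp_ei_propose(Xobs, yobs, rng)
        Xobs = np.vstack([Xobs, u])
        yobs = np.append(yobs, cv_accuracy(u))
    for u, a in zip(Xobs, yobs):
        logC, logG = _BOUNDS[:, 0] + u * (_BOUNDS[:, 1] - _BOUNDS[:, 0])
        history.append((float(10.0**logC), float(10.0**logG), float(a)))
    u_best = Xobs[int(np.argmax(yobs))]
    logC, logG = _BOUNDS[:, 0] + u_best * (_BOUNDS[:, 1] - _BOUNDS[:, 0])
    C, gamma = float(10.0**logC), float(10.0**logG)

    alpha, b = _fit_svm_raw(X, y, C, gamma, seed=seed)
    model = EsvmModel(X, 2.0 * y - 1.0, alpha, b, C, gamma, search_history=history)
    if val is not None:
        model.platt = _platt_calibrate(model, val)
    return model


def _platt_calibrate(model: EsvmModel, val: Cohort | tuple) -> LogitFit:
    Xv, yv = _as_xy(val)
    s = model.decision(Xv)
    return fit_logistic(s[:, None], yv, add_intercept=True)


def fit_svm_baseline(
    train: Cohort | tuple, val: Cohort | tuple | None = None,
    C: float = 1.0, gamma: float | None = None, seed: int = DEFAULT_SEED,
) -> EsvmModel:
    """Fixed-hyperparameter RBF SVM (C=1, gamma=1/d) with Platt calibration."""
    X, y = _as_xy(train)
    if len(y) > SVM_MAX_N:
        raise ValueError(f"dense solver limited to n <= {SVM_MAX_N}")
    gamma = gamma if gamma is not None else 1.0 / X.shape[1]
    alpha, b = _fit_svm_raw(X, y, C, gamma, seed=seed)
    model = EsvmModel(X, 2.0 * y - 1.0, alpha, b, C, gamma)
    if val is not None:
        model.platt = _platt_calibrate(model, val)
    return model
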