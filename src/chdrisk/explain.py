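"""Model-agnostic explainability: Shapley-value feature attribution and a
global surrogate decision tree with a fidelity score.

Attribution satisfies local accuracy ``f(x) = phi_0 + sum_i phi_i`` where
``phi_0`` is the mean model output over a background set and absent features
are marginalised by substituting background values.  The exact variant
enumerates all 2^M coalitions (M <= 12); the sampling variant averages
marginal contributions over random feature permutations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .cohort import Cohort
from .learners import CartModel, fit_cart


@dataclass
class ShapExplanation:
    base_value: float
    attributions: np.ndarray
    model_output: float
    method: str
    n_perm: int | None = None
    seed: int | None = None

    def local_accuracy_gap(self) -> float:
        return abs(self.model_output - self.base_value - self.attributions.sum())


def _coalition_value(predict_fn, x, background, members: np.ndarray) -> float:
    """Mean prediction with features in ``members`` fixed to x, the rest
    drawn from the background rows."""
    Xb = background.copy()
    Xb[:, members] = x[members]
    return float(np.mean(predict_fn(Xb)))


def shap_exact(predict_fn, x: np.ndarray, background: np.ndarray) -> ShapExplanation:
    """Classical Shapley values by full coalition enumeration (M <= 12)."""
    x = np.asarray(x, dtype=float).ravel()
    background = np.atleast_2d(np.asarray(background, dtype=float))
    M = x.size
    if M > 12:
        raise ValueError("exact enumeration limited to M <= 12 features; use shap_sample")
    # cache v(S) for all subsets
    values: dict[frozenset, float] = {}
    feats = list(range(M))
    for r in range(M + 1):
        for S in itertools.combinations(feats, r):
            values[frozenset(S)] = _coalition_value(
                predict_fn, x, background, np.array(S, dtype=int)
            )
    phi = np.zeros(M)
    fact = math.factorial
    for i in feats:
        rest = [j for j in feats if j != i]
        for r in range(M):
            w = fact(r) * fact(M - r - 1) / fact(M)
            for S in itertools.combinations(rest, r):
                fs = frozenset(S)
                phi[i] += w * (values[fs | {i}] - values[fs])
    base = values[frozenset()]
    out = values[frozenset(feats)]
    return ShapExplanation(base, phi, out, "exact")


def shap_sample(
    predict_fn, x: np.ndarray, background: np.ndarray, n_perm: int = 200, seed: int = 2025
) -> ShapExplanation:
    """Permutation-sampling Shapley estimator.

    For each random feature permutation, marginal contributions of adding
    features one at a time (absent features marginalised over the
    background) are accumulated; the average over permutations estimates
    phi.  Attributions are recentred so local accuracy holds exactly.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = np.asarray(x, dtype=float).ravel()
    background = np.atleast_2d(np.asarray(background, dtype=float))
    M = x.size
    rng = np.random.default_rng(seed)
    phi = np.zeros(M)
    base = float(np.mean(predict_fn(background)))
    out = float(np.mean(predict_fn(np.atleast_2d(x))))
    for _ in range(n_perm):
        perm = rng.permutation(M)
        Xb = background.copy()
        prev = base
        for i in perm:
            Xb[:, i] = x[i]
            cur = float(np.mean(predict_fn(Xb)))
            phi[i] += cur - prev
            prev = cur
    phi /= n_perm
    # exact-sum correction spreads the Monte-Carlo residual evenly
    phi += (out - base - phi.sum()) / M
    return ShapExplanation(base, phi, out, "sampling", n_perm=n_perm, seed=seed)


def mean_abs_shap(explanations: list[ShapExplanation],
                  feature_names: list[str] | None = None) -> list[tuple[str, float]]:
    """Global ranking: mean |phi_i| per feature, descending (ties by index)."""
    if not explanations:
        raise ValueError("need at least one explanation")
    A = np.stack([e.attributions for e in explanations])
    mean_abs = np.abs(A).mean(axis=0)
    names = feature_names or [f"x{j}" for j in range(A.shape[1])]
    order = sorted(range(A.shape[1]), key=lambda j: (-mean_abs[j], j))
    return [(names[j], float(mean_abs[j])) for j in order]


@dataclass
class SurrogateReport:
    tree: CartModel
    fidelity: float
    max_depth: int
    fit_indices: np.ndarray | None = None

    def rules(self, feature_names: list[str]) -> str:
        lines: list[str] = []

        def walk(node, indent: int) -> None:
            pad = "  " * indent
            if node.is_leaf:
                lines.append(f"{pad}predict class {int(node.value[1] >= 0.5)} "
                             f"(p1={node.value[1]:.3f}, n={node.n})")
                return
            lines.append(f"{pad}if {feature_names[node.feature]} <= {node.theta:.4g}:")
            walk(node.left, indent + 1)
            lines.append(f"{pad}else:")
            walk(node.right, indent + 1)

        walk(self.tree.root, 0)
        return "\n".join(lines)


def surrogate_tree(
    predict_fn, cohort: Cohort, max_depth: int = 4, seed: int = 2025
) -> SurrogateReport:
    """Fit a hard CART of limited depth to the explained model's predicted
    labels; fidelity = label agreement on a held-out half of the cohort."""
    labels = (np.asarray(predict_fn(cohort.features)) >= 0.5).astype(int)
    rng = np.random.default_rng(seed)
    idx = rng.permutation(cohort.n)
    half = cohort.n // 2
    fit_idx, eval_idx = idx[:half], idx[half:]
    if len(np.unique(labels[fit_idx])) < 2:
        # constant model: a single-leaf tree is a perfect surrogate
        tree = fit_cart((cohort.features[fit_idx], labels[fit_idx]), max_depth=0, min_leaf=1)
    else:
        tree = fit_cart(
            (cohort.features[fit_idx], labels[fit_idx]), max_depth=max_depth, min_leaf=1
        )
    agree = (tree.predict(cohort.features[eval_idx]) == labels[eval_idx]).mean()
    return SurrogateReport(tree, float(agree), max_depth, fit_idx)
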