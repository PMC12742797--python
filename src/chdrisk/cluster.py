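"""Risk-subgroup analysis: domain-wise k-means, silhouette-based k
selection, chi-square association with the outcome, and cluster-dummy
logistic regression reported as coefficients / odds ratios / Wald CIs.

Features are encoded before clustering: z-score for continuous and ordinal
columns, binary columns passed through (they are already 0/1 indicators).
K-means minimises the within-cluster sum of squares J = sum_i sum_{x in C_i}
||x - mu_i||^2 by Lloyd iterations from k-means++ seeding, best of several
restarts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from ._glm import fit_logistic
from .cohort import Cohort

Z_95 = 1.96


@dataclass
class KMeansModel:
    k: int
    centroids: np.ndarray
    assignments: np.ndarray
    objective: float
    iterations: int
    seed: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        d2 = ((X[:, None, :] - self.centroids[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)


def _kmeans_pp(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = len(X)
    centers = [X[int(rng.integers(n))]]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for _ in range(1, k):
        p = d2 / d2.sum() if d2.sum() > 0 else np.full(n, 1.0 / n)
        centers.append(X[int(rng.choice(n, p=p))])
        d2 = np.minimum(d2, ((X - centers[-1]) ** 2).sum(axis=1))
    return np.array(centers)


def _lloyd(X: np.ndarray, centers: np.ndarray, max_iter: int) -> tuple[np.ndarray, np.ndarray, float, int]:
    k = len(centers)
    labels = np.zeros(len(X), dtype=int)
    it = 0
    for it in range(1, max_iter + 1):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        # empty-cluster repair: reseed at the farthest point
        for c in range(k):
            if not (new_labels == c).any():
                far = int(d2[np.arange(len(X)), new_labels].argmax())
                centers[c] = X[far]
                new_labels[far] = c
        if it > 1 and (new_labels == labels).all():
            labels = new_labels
            break
        labels = new_labels
        for c in range(k):
            centers[c] = X[labels == c].mean(axis=0)
    J = float(((X - centers[labels]) ** 2).sum())
    return labels, centers, J, it


def kmeans(
    X: np.ndarray, k: int, seed: int = 2025, max_iter: int = 300, restarts: int = 10
) -> KMeansModel:
    """Lloyd iterations from k-means++ seeding; best of ``restarts`` by J."""
    X = np.asarray(X, dtype=float)
    n_distinct = len(np.unique(X, axis=0))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct rows")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(restarts):
        centers = _kmeans_pp(X, k, rng)
        labels, centers, J, it = _lloyd(X, centers.copy(), max_iter)
        if best is None or J < best[2]:
            best = (labels, centers, J, it)
    labels, centers, J, it = best
    return KMeansModel(k, centers, labels, J, it, seed)


def silhouette(X: np.ndarray, assignments: np.ndarray) -> float:
    """Mean silhouette (b - a) / max(a, b); singleton clusters contribute 0;
    points with a == b == 0 (coincident clusters) contribute 0."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(assignments, dtype=int)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    D = np.sqrt(
        np.maximum(
            ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2), 0.0
        )
    )
    n = len(X)
    s = np.zeros(n)
    sizes = {c: int((labels == c).sum()) for c in uniq}
    for i in range(n):
        c = labels[i]
        if sizes[c] == 1:
            s[i] = 0.0
            continue
        same = labels == c
        a = D[i, same].sum() / (sizes[c] - 1)
        b = min(D[i, labels == other].mean() for other in uniq if other != c)
        m = max(a, b)
        s[i] = 0.0 if m == 0 else (b - a) / m
    return float(s.mean())


def select_k(
    X: np.ndarray, k_range: range = range(2, 11), seed: int = 2025, restarts: int = 5
) -> tuple[int, dict[int, float]]:
    """k with the largest mean silhouette; ties resolved toward smaller k."""
    if len(k_range) == 0:
        raise ValueError("empty k range")
    scores: dict[int, float] = {}
    for k in k_range:
        try:
            model = kmeans(X, k, seed=seed, restarts=restarts)
        except ValueError:
            continue
        scores[k] = silhouette(X, model.assignments)
    best_k = max(sorted(scores), key=lambda k: scores[k])  # sorted => ties to smaller k
    return best_k, scores


def chisq_association(assignments: np.ndarray, outcome: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square of the k x 2 cluster-by-outcome table."""
    labels = np.asarray(assignments, dtype=int)
    y = np.asarray(outcome, dtype=int)
    clusters = np.unique(labels)
    table = np.array([
        [int(((labels == c) & (y == 0)).sum()), int(((labels == c) & (y == 1)).sum())]
        for c in clusters
    ], dtype=float)
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ValueError("chi-square table has an empty row or column")
    expected = table.sum(axis=1)[:, None] * table.sum(axis=0)[None, :] / table.sum()
    stat = float(((table - expected) ** 2 / expected).sum())
    df = len(clusters) - 1
    p = float(chi2.sf(stat, df))
    return stat, df, p


def cluster_logit(assignments: np.ndarray, outcome: np.ndarray) -> pd.DataFrame:
    """Logistic regression of the outcome on k-1 cluster dummies (cluster 0
    reference) with Wald standard errors; OR = exp(coef), 95% CI =
    exp(coef +/- 1.96 SE).  Complete separation falls back to a
    ridge-stabilised fit, flagged in the ``ridged`` attribute of the frame.
    """
    labels = np.asarray(assignments, dtype=int)
    y = np.asarray(outcome, dtype=int)
    clusters = np.unique(labels)
    if clusters[0] != 0 or not (labels == 0).any():
        raise ValueError("reference cluster (label 0) must be nonempty")
    dummies = np.column_stack([(labels == c).astype(float) for c in clusters[1:]])
    fit = fit_logistic(dummies, y, add_intercept=True)
    se = np.sqrt(np.diag(fit.cov))
    from scipy.stats import norm as _norm

    rows = []
    names = ["Intercept"] + [f"Cluster {c}" for c in clusters[1:]]
    with np.errstate(over="ignore"):   # separation can push a CI bound to inf
        for name, coef, s in zip(names, fit.coef, se):
            z = coef / s if s > 0 else np.inf
            rows.append(
                {
                    "term": name,
                    "coef": coef,
                    "std_err": s,
                    "p_value": 2.0 * _norm.sf(abs(z)),
                    "odds_ratio": np.exp(coef),
                    "ci_lower": np.exp(coef - Z_95 * s),
                    "ci_upper": np.exp(coef + Z_95 * s),
                }
            )
    df = pd.DataFrame(rows)
    df.attrs["ridged"] = fit.ridged
    return df


@dataclass
class ClusterReport:
    domain: str
    k: int
    silhouette: float
    chi2_stat: float
    chi2_df: int
    chi2_p: float
    logit_table: pd.DataFrame
    assignments: np.ndarray = field(repr=False, default=None)


def encode_for_clustering(cohort: Cohort, cols: list[int]) -> np.ndarray:
    """Z-score continuous/ordinal columns, pass binary columns through."""
    X = cohort.features[:, cols].copy()
    for jj, j in enumerate(cols):
        if cohort.feature_kinds[j] == "binary":
            continue
        col = X[:, jj]
        sd = col.std(ddof=0)
        X[:, jj] = (col - col.mean()) / (sd if sd > 0 else 1.0)
    return X


def analyze_domains(
    cohort: Cohort,
    domains: tuple[str, ...] = ("demographic", "clinical", "behavioral", "healthcare", "full"),
    k_range: range = range(2, 11),
    seed: int = 2025,
    restarts: int = 5,
) -> list[ClusterReport]:
    """Domain-wise clustering plus the integrative full-feature run, each with
    silhouette-selected k, chi-square association, and the logistic table."""
    reports = []
    for dom in domains:
        cols = (
            list(range(cohort.d)) if dom == "full" else cohort.domain_columns(dom)
        )
        if not cols:
            continue
        X = encode_for_clustering(cohort, cols)
        k, _scores = select_k(X, k_range=k_range, seed=seed, restarts=restarts)
        model = kmeans(X, k, seed=seed, restarts=restarts)
        # relabel so cluster 0 is the largest (stable reference)
        order = np.argsort(-np.bincount(model.assignments, minlength=k), kind="stable")
        relabel = np.empty(k, dtype=int)
        relabel[order] = np.arange(k)
        labels = relabel[model.assignments]
        stat, dof, p = chisq_association(labels, cohort.outcome)
        table = cluster_logit(labels, cohort.outcome)
        reports.append(
            ClusterReport(dom, k, silhouette(X, labels), stat, dof, p, table, labels)
        )
    return reports
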