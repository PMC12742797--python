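"""Evaluation: confusion-matrix metrics, ROC/AUC, precision-recall,
calibration curves, and learning curves.

Conventions: a score >= threshold (default 0.5) predicts positive; metrics
with a zero denominator are reported as NaN ("missing") with a warning
rather than 0, so fold averages are not silently deflated; AUC uses the
tie-corrected Mann-Whitney rank formulation, which coincides with the
trapezoidal area under the empirical ROC curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .cohort import Cohort
from .resample import kfold, stratified_subsample


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be nonnegative")
        if self.tp + self.fn + self.fp + self.tn == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def confusion(y_true: np.ndarray, y_score: np.ndarray, threshold: float = 0.5) -> ConfusionMatrix:
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(y_score, dtype=float)
    if y.size == 0:
        raise ValueError("empty input")
    if y.shape != s.shape:
        raise ValueError("y_true and y_score must align")
    pred = s >= threshold
    return ConfusionMatrix(
        tp=int((pred & (y == 1)).sum()),
        fn=int((~pred & (y == 1)).sum()),
        fp=int((pred & (y == 0)).sum()),
        tn=int((~pred & (y == 0)).sum()),
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN")
        return float("nan")
    return num / den


def sensitivity(cm: ConfusionMatrix) -> float:
    return _ratio(cm.tp, cm.tp + cm.fn, "sensitivity")


def specificity(cm: ConfusionMatrix) -> float:
    return _ratio(cm.tn, cm.tn + cm.fp, "specificity")


def accuracy(cm: ConfusionMatrix) -> float:
    return _ratio(cm.tp + cm.tn, cm.total, "accuracy")


def precision(cm: ConfusionMatrix) -> float:
    return _ratio(cm.tp, cm.tp + cm.fp, "precision")


def f1(cm: ConfusionMatrix) -> float:
    return _ratio(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn, "f1")


def metric_report(y_true: np.ndarray, y_score: np.ndarray, threshold: float = 0.5) -> dict:
    cm = confusion(y_true, y_score, threshold)
    rep = {
        "sensitivity": sensitivity(cm),
        "specificity": specificity(cm),
        "accuracy": accuracy(cm),
        "precision": precision(cm),
        "f1": f1(cm),
        "threshold": threshold,
    }
    y = np.asarray(y_true, dtype=int)
    if 0 < y.sum() < y.size:
        rep["auc_roc"] = roc_auc(y_true, y_score)[0]
        rep["avg_precision"] = pr_curve(y_true, y_score)[1]
    else:
        rep["auc_roc"] = float("nan")
        rep["avg_precision"] = float("nan")
    return rep


def roc_auc(y_true: np.ndarray, y_score: np.ndarray) -> tuple[float, np.ndarray]:
    """AUC via the tie-corrected Mann-Whitney statistic, plus the ROC curve
    points (FPR, TPR) over all score thresholds."""
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(y_score, dtype=float)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(s)
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    # curve: sweep descending unique thresholds, ties cross simultaneously
    order = np.argsort(-s, kind="stable")
    ys = y[order]
    tps = np.cumsum(ys)
    fps = np.cumsum(1 - ys)
    distinct = np.r_[np.flatnonzero(np.diff(s[order]) != 0), len(ys) - 1]
    tpr = np.r_[0.0, tps[distinct] / n1]
    fpr = np.r_[0.0, fps[distinct] / n0]
    curve = np.column_stack([fpr, tpr])
    return float(auc), curve


def pr_curve(y_true: np.ndarray, y_score: np.ndarray) -> tuple[np.ndarray, float]:
    """Precision-recall curve and step-interpolated average precision
    AP = sum_k (R_k - R_{k-1}) P_k over descending score thresholds."""
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(y_score, dtype=float)
    n1 = int(y.sum())
    if n1 == 0:
        raise ValueError("no positive labels")
    order = np.argsort(-s, kind="stable")
    ys = y[order]
    tps = np.cumsum(ys)
    fps = np.cumsum(1 - ys)
    distinct = np.r_[np.flatnonzero(np.diff(s[order]) != 0), len(ys) - 1]
    prec = tps[distinct] / (tps[distinct] + fps[distinct])
    rec = tps[distinct] / n1
    ap = float(np.sum(np.diff(np.r_[0.0, rec]) * prec))
    return np.column_stack([rec, prec]), ap


def calibration_curve(
    y_true: np.ndarray, y_score: np.ndarray, bins: int = 10
) -> np.ndarray:
    """(mean predicted, observed frequency) per nonempty equal-width bin."""
    y = np.asarray(y_true, dtype=float)
    s = np.asarray(y_score, dtype=float)
    if ((s < 0) | (s > 1)).any():
        raise ValueError("scores must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, bins + 1)
    which = np.clip(np.digitize(s, edges[1:-1], right=False), 0, bins - 1)
    pts = []
    for b in range(bins):
        m = which == b
        if m.any():
            pts.append((s[m].mean(), y[m].mean()))
    return np.array(pts)


def learning_curve(
    fit_fn,
    cohort: Cohort,
    fractions: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
    folds: int = 5,
    seed: int = 2025,
) -> list[dict]:
    """Nested subsample -> k-fold CV; mean train and CV accuracy per fraction.

    ``fit_fn(train_cohort)`` must return a model with ``predict_proba``.
    Infeasible fractions (too small for stratified folds) are skipped with a
    warning.
    """
    out = []
    for frac in fractions:
        n_sub = max(2, int(round(frac * cohort.n)))
        try:
            sub = (
                cohort if n_sub >= cohort.n else stratified_subsample(cohort, n_sub, seed=seed)
            )
            splits = kfold(sub, folds=folds, seed=seed)
        except ValueError as exc:
            warnings.warn(f"fraction {frac} skipped: {exc}")
            continue
        tr_scores, cv_scores = [], []
        for fit_part, held_part in splits:
            model = fit_fn(fit_part)
            tr_pred = (model.predict_proba(fit_part.features) >= 0.5).astype(int)
            cv_pred = (model.predict_proba(held_part.features) >= 0.5).astype(int)
            tr_scores.append((tr_pred == fit_part.outcome).mean())
            cv_scores.append((cv_pred == held_part.outcome).mean())
        out.append(
            {
                "fraction": frac,
                "n": sub.n,
                "train_score": float(np.mean(tr_scores)),
                "cv_score": float(np.mean(cv_scores)),
            }
        )
    return out
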