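"""Internal IRLS logistic-regression solver shared across modules.

Used by the stacking meta-learner, cluster-dummy logistic tables, and
Platt-style score calibration.  Convergence: relative log-likelihood change
below 1e-10 or 100 iterations.  On (near-)separation the solve is repeated
with a small ridge and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class LogitFit:
    coef: np.ndarray            # includes intercept as coef[0] iff add_intercept
    cov: np.ndarray             # inverse observed information (Wald covariance)
    log_likelihood: float
    iterations: int
    converged: bool
    ridged: bool                # True when ridge stabilisation was applied

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        z = np.clip(X @ self.coef, -500, 500)
        return 1.0 / (1.0 + np.exp(-z))


def _irls(X: np.ndarray, y: np.ndarray, ridge: float, tol: float = 1e-10,
          max_iter: int = 100) -> tuple[np.ndarray, np.ndarray, float, int, bool]:
    n, p = X.shape
    beta = np.zeros(p)
    ll_old = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1.0 - mu)
        W = np.maximum(W, 1e-12)
        H = X.T @ (X * W[:, None]) + ridge * np.eye(p)
        grad = X.T @ (y - mu) - ridge * beta
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        beta = beta + step
        eta = np.clip(X @ beta, -30, 30)
        mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
        ll = float(y @ np.log(mu) + (1 - y) @ np.log(1 - mu))
        if np.isfinite(ll_old) and abs(ll - ll_old) <= tol * (abs(ll_old) + 1e-12):
            ll_old = ll
            return beta, H, ll, it, True
        ll_old = ll
    return beta, H, ll_old, it, False


def fit_logistic(X: np.ndarray, y: np.ndarray, add_intercept: bool = True,
                 ridge: float = 0.0) -> LogitFit:
    """Binary logistic regression by iteratively reweighted least squares.

    If the unpenalised fit diverges (separation shows up as exploding
    coefficients or a non-converged solve), it is rerun with ridge 1e-6 * n
    and flagged on the result.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if add_intercept:
        X = np.column_stack([np.ones(len(X)), X])
    beta, H, ll, it, conv = _irls(X, y, ridge)
    ridged = ridge > 0
    # |coef| beyond ~25 on any reasonable design signals (quasi-)separation
    if not conv or not np.isfinite(beta).all() or np.abs(beta).max() > 25:
        beta, H, ll, it, conv = _irls(X, y, max(ridge, 1e-6 * len(y)))
        ridged = True
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    return LogitFit(beta, cov, ll, it, conv, ridged)
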