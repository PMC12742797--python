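"""Cohort container, CSV I/O, and preprocessing operators.

A :class:`Cohort` is the universal input of the pipeline: an ``n x d`` feature
matrix with a binary outcome and per-feature metadata (kind and risk domain).
Preprocessing covers k-nearest-neighbour imputation, IQR and Mahalanobis
outlier flagging, variance-threshold feature removal, and z-score / min-max
scaling.  Outlier flags are reported, never silently applied: the caller (or
the CLI ``--drop-outliers`` flag) decides whether flagged rows are removed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy import stats

KINDS = ("binary", "ordinal", "continuous")
DOMAINS = ("demographic", "clinical", "behavioral", "healthcare")

OUTCOME = "outcome"


class SchemaError(ValueError):
    """Raised when a CSV/schema pair violates the cohort contract."""


@dataclass
class Cohort:
    """Tabular cohort: features, binary outcome, per-feature metadata.

    Parameters
    ----------
    features : ndarray of shape (n, d)
        Real-valued feature matrix; missing cells are NaN until imputation.
    outcome : ndarray of shape (n,)
        Strictly binary labels in {0, 1}.
    feature_names : list of str
        Unique column labels.
    feature_kinds : list of str
        One of ``binary``, ``ordinal``, ``continuous`` per feature.
    feature_domains : list of str
        One of ``demographic``, ``clinical``, ``behavioral``, ``healthcare``.
    """

    features: np.ndarray
    outcome: np.ndarray
    feature_names: list[str]
    feature_kinds: list[str]
    feature_domains: list[str]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.outcome = np.asarray(self.outcome)
        if self.features.ndim != 2:
            raise SchemaError("features must be a 2-D matrix")
        n, d = self.features.shape
        if d < 1 or n < 2:
            raise SchemaError(f"cohort needs n >= 2 rows and d >= 1 features, got {n}x{d}")
        if len(self.feature_names) != d or len(self.feature_kinds) != d or len(self.feature_domains) != d:
            raise SchemaError("metadata length mismatch with feature matrix")
        if len(set(self.feature_names)) != d:
            raise SchemaError("feature names must be unique")
        for k in self.feature_kinds:
            if k not in KINDS:
                raise SchemaError(f"unknown feature kind {k!r}")
        for dom in self.feature_domains:
            if dom not in DOMAINS:
                raise SchemaError(f"unknown feature domain {dom!r}")
        out = self.outcome
        if out.shape != (n,) or not np.isin(out[~pd.isna(out)], [0, 1]).all() or pd.isna(out).any():
            raise SchemaError("outcome must be a length-n strictly binary vector")
        self.outcome = out.astype(int)

    # -- convenience -------------------------------------------------------
    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def d(self) -> int:
        return self.features.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.features[:, self.feature_names.index(name)]

    def kind_mask(self, kind: str) -> np.ndarray:
        return np.array([k == kind for k in self.feature_kinds])

    def domain_columns(self, domain: str) -> list[int]:
        return [j for j, d in enumerate(self.feature_domains) if d == domain]

    def take_rows(self, idx: np.ndarray) -> "Cohort":
        return replace(self, features=self.features[idx], outcome=self.outcome[idx])

    def take_features(self, cols: list[int]) -> "Cohort":
        return Cohort(
            self.features[:, cols],
            self.outcome,
            [self.feature_names[j] for j in cols],
            [self.feature_kinds[j] for j in cols],
            [self.feature_domains[j] for j in cols],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=self.feature_names)
        df[OUTCOME] = self.outcome
        return df

    def schema(self) -> dict:
        return {
            name: {"kind": kind, "domain": dom}
            for name, kind, dom in zip(self.feature_names, self.feature_kinds, self.feature_domains)
        }


@dataclass
class PreprocessReport:
    """Audit trail of the preprocessing stages applied to a cohort."""

    imputed_cells: int = 0
    iqr_outlier_rows: list[int] = field(default_factory=list)
    mahalanobis_outlier_rows: list[int] = field(default_factory=list)
    dropped_low_variance: list[str] = field(default_factory=list)
    scaling: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "imputed_cells": self.imputed_cells,
                "iqr_outlier_rows": list(map(int, self.iqr_outlier_rows)),
                "mahalanobis_outlier_rows": list(map(int, self.mahalanobis_outlier_rows)),
                "dropped_low_variance": self.dropped_low_variance,
                "scaling": {k: [float(c), float(s)] for k, (c, s) in self.scaling.items()},
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_schema(path: str) -> dict:
    """Read a YAML schema file mapping column -> {kind, domain}."""
    with open(path) as fh:
        return yaml.safe_load(fh)


def read_cohort(path: str, schema: dict) -> Cohort:
    """Read a cohort CSV using a ``column -> {kind, domain}`` schema map.

    The outcome column must be binary after numeric coercion; missing cells
    become NaN sentinels for downstream imputation.
    """
    df = pd.read_csv(path)
    unknown = set(schema) - set(df.columns)
    if unknown:
        raise SchemaError(f"schema columns absent from CSV: {sorted(unknown)}")
    names = [c for c in df.columns if c != OUTCOME and c in schema]
    if OUTCOME not in df.columns:
        raise SchemaError("outcome column missing")
    out = pd.to_numeric(df[OUTCOME], errors="coerce")
    observed = out.dropna().unique()
    if not np.isin(observed, [0, 1]).all() or out.isna().any():
        raise SchemaError("outcome column is not strictly binary")
    feats = df[names].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    return Cohort(
        feats,
        out.to_numpy(),
        names,
        [schema[c]["kind"] for c in names],
        [schema[c]["domain"] for c in names],
    )


def write_cohort(cohort: Cohort, path: str, schema_path: str | None = None) -> None:
    cohort.to_frame().to_csv(path, index=False)
    if schema_path is not None:
        with open(schema_path, "w") as fh:
            yaml.safe_dump(cohort.schema(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

def impute_knn(cohort: Cohort, k: int = 5, report: PreprocessReport | None = None) -> Cohort:
    """Fill missing cells from the k nearest complete rows.

    Distance is Euclidean on co-observed features against rows with no
    missing values.  Continuous cells get the neighbour mean; binary and
    ordinal cells get the neighbour mode, ties broken toward the smaller
    category value.  Observed cells are never changed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = cohort.features
    miss = np.isnan(X)
    if not miss.any():
        return cohort
    all_missing = miss.all(axis=0)
    if all_missing.any():
        j = int(np.flatnonzero(all_missing)[0])
        raise ValueError(f"column {cohort.feature_names[j]!r} is entirely missing")
    if (miss.all(axis=1)).any():
        raise ValueError("every row must have at least one observed feature")
    complete = ~miss.any(axis=1)
    if complete.sum() < 1:
        raise ValueError("no complete rows available as imputation donors")
    donors = X[complete]
    kk = min(k, donors.shape[0])
    out = X.copy()
    n_imputed = 0
    for i in np.flatnonzero(miss.any(axis=1)):
        obs = ~miss[i]
        diff = donors[:, obs] - X[i, obs]
        dist = np.sqrt((diff * diff).sum(axis=1))
        nn = np.argsort(dist, kind="stable")[:kk]
        for j in np.flatnonzero(miss[i]):
            vals = donors[nn, j]
            if cohort.feature_kinds[j] == "continuous":
                out[i, j] = vals.mean()
            else:
                uniq, counts = np.unique(vals, return_counts=True)
                out[i, j] = uniq[counts == counts.max()].min()
            n_imputed += 1
    if report is not None:
        report.imputed_cells += n_imputed
    return replace(cohort, features=out)


# ---------------------------------------------------------------------------
# Outlier flags
# ---------------------------------------------------------------------------

def flag_outliers_iqr(values: np.ndarray, multiplier: float = 1.5) -> np.ndarray:
    """Row indices outside [Q1 - m*IQR, Q3 + m*IQR] (type-7 quantiles)."""
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if finite.sum() < 4:
        raise ValueError("need at least 4 finite values")
    q1, q3 = np.quantile(v[finite], [0.25, 0.75])  # numpy default = linear/type-7
    iqr = q3 - q1
    lo, hi = q1 - multiplier * iqr, q3 + multiplier * iqr
    return np.flatnonzero(finite & ((v < lo) | (v > hi)))


def flag_outliers_mahalanobis(
    cohort: Cohort, alpha: float = 0.01, ridge: bool = True
) -> np.ndarray:
    """Rows whose squared Mahalanobis distance on continuous features exceeds
    the chi-square(d_cont) upper-``alpha`` quantile.

    A singular covariance is ridge-regularised with ``1e-6 * trace(S)/d`` on
    the diagonal unless ``ridge`` is disabled, in which case it is an error.
    """
    cols = np.flatnonzero(cohort.kind_mask("continuous"))
    if cols.size == 0:
        return np.array([], dtype=int)
    X = cohort.features[:, cols]
    mu = X.mean(axis=0)
    S = np.cov(X, rowvar=False)
    S = np.atleast_2d(S)
    d = S.shape[0]
    try:
        if np.linalg.matrix_rank(S) < d or X.shape[0] <= d:
            raise np.linalg.LinAlgError("singular covariance")
        Sinv = np.linalg.inv(S)
    except np.linalg.LinAlgError:
        if not ridge:
            raise ValueError("singular covariance of continuous features; enable ridge")
        S = S + np.eye(d) * (1e-6 * np.trace(S) / d)
        Sinv = np.linalg.inv(S)
    delta = X - mu
    d2 = np.einsum("ij,jk,ik->i", delta, Sinv, delta)
    cut = stats.chi2.ppf(1.0 - alpha, df=d)
    return np.flatnonzero(d2 > cut)


# ---------------------------------------------------------------------------
# Feature filtering and scaling
# ---------------------------------------------------------------------------

def variance_filter(
    cohort: Cohort, threshold: float = 0.0
) -> tuple[Cohort, list[str]]:
    """Drop features whose sample variance is <= ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    var = cohort.features.var(axis=0, ddof=1)
    keep = [j for j in range(cohort.d) if var[j] > threshold]
    dropped = [cohort.feature_names[j] for j in range(cohort.d) if var[j] <= threshold]
    if not keep:
        raise ValueError("variance filter would drop every feature")
    return cohort.take_features(keep), dropped


def standardize(
    cohort: Cohort, mode: str = "zscore", report: PreprocessReport | None = None
) -> Cohort:
    """Scale continuous/ordinal features; binary features are untouched.

    ``zscore`` centres to mean 0 / sd 1 (error on a constant continuous
    feature); ``minmax`` maps the observed range onto [0, 1] (constant
    features map to 0).  The (center, scale) pair per scaled feature is
    recorded on the report when one is supplied.
    """
    if mode not in ("zscore", "minmax"):
        raise ValueError(f"unknown scaling mode {mode!r}")
    X = cohort.features.copy()
    for j, (name, kind) in enumerate(zip(cohort.feature_names, cohort.feature_kinds)):
        if kind == "binary":
            continue
        col = X[:, j]
        if mode == "zscore":
            c, s = col.mean(), col.std(ddof=0)
            if s == 0:
                if kind == "continuous":
                    raise ValueError(f"constant continuous feature {name!r} under zscore")
                s = 1.0
        else:
            c, s = col.min(), col.max() - col.min()
            if s == 0:
                s = 1.0
        X[:, j] = (col - c) / s
        if report is not None:
            report.scaling[name] = (float(c), float(s))
    return replace(cohort, features=X)


def preprocess(
    cohort: Cohort,
    knn_k: int = 5,
    iqr_multiplier: float = 1.5,
    mahalanobis_alpha: float = 0.01,
    variance_threshold: float = 0.0,
    scaling: str = "zscore",
    drop_outliers: bool = False,
) -> tuple[Cohort, PreprocessReport]:
    """Full preprocessing pipeline: impute -> flag -> filter -> scale."""
    report = PreprocessReport()
    cohort = impute_knn(cohort, k=knn_k, report=report)
    iqr_rows: set[int] = set()
    for j, kind in enumerate(cohort.feature_kinds):
        if kind == "continuous":
            try:
                iqr_rows |= set(flag_outliers_iqr(cohort.features[:, j], iqr_multiplier).tolist())
            except ValueError:
                warnings.warn(f"IQR flag skipped for {cohort.feature_names[j]!r}: too few values")
    report.iqr_outlier_rows = sorted(iqr_rows)
    report.mahalanobis_outlier_rows = flag_outliers_mahalanobis(
        cohort, alpha=mahalanobis_alpha
    ).tolist()
    cohort, dropped = variance_filter(cohort, variance_threshold)
    report.dropped_low_variance = dropped
    if drop_outliers:
        bad = sorted(set(report.iqr_outlier_rows) | set(report.mahalanobis_outlier_rows))
        keep = np.setdiff1d(np.arange(cohort.n), np.array(bad, dtype=int))
        cohort = cohort.take_rows(keep)
    cohort = standardize(cohort, mode=scaling, report=report)
    return cohort, report
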