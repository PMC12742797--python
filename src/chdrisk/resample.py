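"""Class re-balancing and sampling: SMOTE, Yamane sizing, stratified
subsampling, the 70/15/15 split, and stratified k-fold cross-validation.

SMOTE synthesises minority-class rows by interpolating between a minority
point and one of its k minority-class nearest neighbours:

    x_new = x_i + lambda * (x_nn - x_i),   lambda ~ Uniform[0, 1]

Neighbour search runs on per-feature standardized coordinates so scale does
not dominate; binary features are thresholded at 0.5 after interpolation so
binary kinds stay binary.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace

import numpy as np

from .cohort import Cohort


@dataclass
class SmoteParams:
    k: int = 5
    target_ratio: float = 1.0   # minority/majority after balancing
    seed: int = 2025

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0.0 < self.target_ratio <= 1.0:
            raise ValueError("target_ratio must lie in (0, 1]")


@dataclass
class SplitSpec:
    train: float = 0.70
    val: float = 0.15
    test: float = 0.15
    folds: int = 5
    seed: int = 2025

    def __post_init__(self) -> None:
        if abs(self.train + self.val + self.test - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def smote_interpolate(x_i: np.ndarray, x_nn: np.ndarray, lam: float) -> np.ndarray:
    """One synthetic sample on the segment between x_i and its neighbour."""
    x_i = np.asarray(x_i, dtype=float)
    x_nn = np.asarray(x_nn, dtype=float)
    if x_i.shape != x_nn.shape:
        raise ValueError("x_i and x_nn must have equal dimension")
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    return x_i + lam * (x_nn - x_i)


def smote_balance(cohort: Cohort, params: SmoteParams | None = None) -> Cohort:
    """Oversample the minority class to ``target_ratio`` x majority count.

    Each synthetic row interpolates between a uniformly drawn minority row
    and one of its k minority-class nearest neighbours (Euclidean distance
    on standardized features).  Majority rows are untouched; synthetic rows
    are appended after the originals.  Intended for training data only.
    """
    params = params or SmoteParams()
    y = cohort.outcome
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    minority = 1 if n_pos <= n_neg else 0
    n_min, n_maj = min(n_pos, n_neg), max(n_pos, n_neg)
    if n_min <= params.k:
        raise ValueError(
            f"minority count {n_min} must exceed k={params.k}; use a smaller k"
        )
    target_min = int(round(params.target_ratio * n_maj))
    n_new = target_min - n_min
    if n_new <= 0:
        return cohort
    rng = np.random.default_rng(params.seed)
    idx_min = np.flatnonzero(y == minority)
    Xm = cohort.features[idx_min]
    # neighbour search on standardized coordinates
    sd = cohort.features.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = Xm / sd
    d2 = ((Z[:, None, :] - Z[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    nn = np.argsort(d2, axis=1, kind="stable")[:, : params.k]

    base = rng.integers(0, len(idx_min), size=n_new)
    pick = rng.integers(0, params.k, size=n_new)
    lam = rng.random(n_new)
    x_i = Xm[base]
    x_nn = Xm[nn[base, pick]]
    synth = x_i + lam[:, None] * (x_nn - x_i)
    is_binary = cohort.kind_mask("binary")
    synth[:, is_binary] = (synth[:, is_binary] >= 0.5).astype(float)

    feats = np.vstack([cohort.features, synth])
    out = np.concatenate([y, np.full(n_new, minority, dtype=int)])
    return replace(cohort, features=feats, outcome=out)


def yamane_sample_size(N: int, e: float) -> int:
    """Closed-form sample size n = N / (1 + N e^2), rounded to nearest.

    At N=459,574 and e=0.01 the formula evaluates to 9,787.04; published
    write-ups sometimes round this to ~9,789, but the exact arithmetic is
    what this function returns (9,787).
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if not 0.0 < e < 1.0:
        raise ValueError("e must lie in (0, 1)")
    return int(round(N / (1.0 + N * e * e)))


def _largest_remainder(shares: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``shares``."""
    raw = shares / shares.sum() * total
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:rem]] += 1
    return base


def stratified_subsample(cohort: Cohort, n: int, seed: int = 2025) -> Cohort:
    """Draw n rows with per-outcome-class counts proportional to the cohort
    (largest-remainder rounding), without replacement."""
    if n > cohort.n:
        raise ValueError("n exceeds cohort size")
    classes, counts = np.unique(cohort.outcome, return_counts=True)
    if n < len(classes):
        raise ValueError("n smaller than the number of strata")
    alloc = _largest_remainder(counts.astype(float), n)
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for cls, take in zip(classes, alloc):
        idx = np.flatnonzero(cohort.outcome == cls)
        keep.append(rng.choice(idx, size=int(take), replace=False))
    idx = np.sort(np.concatenate(keep))
    return cohort.take_rows(idx)


def _row_keys(cohort: Cohort, seed: int) -> np.ndarray:
    """Seeded content hash per row.

    Shuffling by content keys (rather than positional RNG draws) makes split
    and fold assignment permutation-equivariant: relabeling rows and then
    splitting gives the relabeled splits.  Ties (duplicate rows) fall back
    to stable positional order.
    """
    salt = int(seed).to_bytes(8, "little", signed=True)
    keys = np.empty(cohort.n, dtype=np.uint64)
    for i in range(cohort.n):
        h = hashlib.blake2b(
            cohort.features[i].tobytes() + bytes([int(cohort.outcome[i])]) + salt,
            digest_size=8,
        )
        keys[i] = int.from_bytes(h.digest(), "little")
    return keys


def split(cohort: Cohort, spec: SplitSpec | None = None) -> tuple[Cohort, Cohort, Cohort]:
    """Disjoint, exhaustive, outcome-stratified train/val/test split."""
    spec = spec or SplitSpec()
    keys = _row_keys(cohort, spec.seed)
    parts: list[list[np.ndarray]] = [[], [], []]
    fracs = np.array([spec.train, spec.val, spec.test])
    for cls in np.unique(cohort.outcome):
        idx = np.flatnonzero(cohort.outcome == cls)
        idx = idx[np.argsort(keys[idx], kind="stable")]
        alloc = _largest_remainder(fracs, len(idx))
        cuts = np.cumsum(alloc)[:-1]
        for part, chunk in zip(parts, np.split(idx, cuts)):
            part.append(chunk)
    splits = tuple(cohort.take_rows(np.sort(np.concatenate(p))) for p in parts)
    for s in splits:
        if len(np.unique(s.outcome)) < 2:
            raise ValueError("a split ended up with a single outcome class")
    return splits


def kfold(cohort: Cohort, folds: int = 5, seed: int = 2025) -> list[tuple[Cohort, Cohort]]:
    """Stratified k-fold partition; each row held out exactly once."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    counts = np.bincount(cohort.outcome)
    if folds > counts[counts > 0].min():
        raise ValueError("folds exceed the minority class count")
    keys = _row_keys(cohort, seed)
    assignment = np.empty(cohort.n, dtype=int)
    for cls in np.unique(cohort.outcome):
        idx = np.flatnonzero(cohort.outcome == cls)
        idx = idx[np.argsort(keys[idx], kind="stable")]
        assignment[idx] = np.arange(len(idx)) % folds
    out = []
    for f in range(folds):
        held = np.flatnonzero(assignment == f)
        fit = np.flatnonzero(assignment != f)
        out.append((cohort.take_rows(fit), cohort.take_rows(held)))
    return out
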