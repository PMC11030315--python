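"""Stratified splitting, cross-validation folds, and SMOTE oversampling.

The training protocol is a 90/10 stratified split into training/CV and
hold-out test, k-fold stratified CV inside the training part, and SMOTE
oversampling of the minority class (antagonists) applied to training data
only.  SMOTE synthesizes minority points as x_i + lambda * (x_j - x_i)
with x_j one of the k nearest minority neighbors of x_i and lambda ~ U[0,1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors


@dataclass
class SplitSpec:
    """Deterministic record of a stratified train/test split (+ optional folds)."""

    train_ids: list
    test_ids: list
    seed: int
    folds: dict | None = None  # id -> fold index

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "train_ids": list(self.train_ids),
                    "test_ids": list(self.test_ids),
                    "seed": self.seed,
                    "folds": self.folds,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitSpec":
        d = json.loads(Path(path).read_text())
        return cls(d["train_ids"], d["test_ids"], d["seed"], d.get("folds"))


def _per_class_test_counts(class_sizes: dict, test_fraction: float, total: int) -> dict:
    """round(size * fraction) per class, largest-remainder corrected so the
    class test counts sum to round(total * fraction)."""
    target_total = int(round(total * test_fraction))
    raw = {c: s * test_fraction for c, s in class_sizes.items()}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    remainders = sorted(raw, key=lambda c: (-(raw[c] - counts[c]), str(c)))
    i = 0
    while sum(counts.values()) < target_total and i < len(remainders):
        c = remainders[i % len(remainders)]
        if counts[c] < class_sizes[c]:
            counts[c] += 1
        i += 1
    return counts


def stratified_split(
    ids: Sequence,
    labels: Sequence,
    test_fraction: float = 0.1,
    seed: int = 0,
    k_folds: int | None = None,
) -> SplitSpec:
    """Per-class sampling without replacement into train/test.

    Per-class test counts are ``round(class_size * test_fraction)`` with a
    largest-remainder correction so the global test size is
    ``round(n * test_fraction)``.  Deterministic given ``seed``.
    """
    ids = list(ids)
    labels = list(labels)
    classes = sorted(set(labels), key=str)
    if len(classes) < 2:
        raise ValueError("stratified split requires both classes")
    rng = np.random.default_rng(seed)
    by_class = {c: [i for i, lab in zip(ids, labels) if lab == c] for c in classes}
    class_sizes = {c: len(v) for c, v in by_class.items()}
    test_counts = _per_class_test_counts(class_sizes, test_fraction, len(ids))
    test_ids, train_ids = [], []
    for c in classes:
        members = list(by_class[c])
        perm = rng.permutation(len(members))
        n_test = test_counts[c]
        test_ids.extend(members[i] for i in perm[:n_test])
        train_ids.extend(members[i] for i in perm[n_test:])
    # restore input order for readability/determinism
    order = {i: k for k, i in enumerate(ids)}
    train_ids.sort(key=lambda i: order[i])
    test_ids.sort(key=lambda i: order[i])
    folds = None
    if k_folds is not None:
        train_labels = [labels[order[i]] for i in train_ids]
        fold_arr = make_folds(train_ids, train_labels, k_folds, seed)
        folds = {str(i): int(f) for i, f in zip(train_ids, fold_arr)}
    return SplitSpec(train_ids, test_ids, seed, folds)


def make_folds(ids: Sequence, labels: Sequence, k: int, seed: int = 0) -> np.ndarray:
    """Stratified k-fold assignment; per-class fold sizes differ by <= 1."""
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = np.asarray(labels)
    for c in np.unique(labels):
        if np.sum(labels == c) < k:
            raise ValueError(f"class {c!r} has fewer than {k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold = np.empty(len(labels), dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        fold[test_idx] = f
    return fold


class SMOTE:
    """Synthetic Minority Oversampling: balance classes by interpolation.

    Each synthetic minority row is ``x_i + lambda * (x_j - x_i)`` for a
    minority sample ``x_i``, one of its ``k_neighbors`` nearest minority
    neighbors ``x_j`` (self excluded), and ``lambda ~ U[0, 1]``.
    Majority rows and the original minority rows pass through unchanged.
    Apply to TRAINING data only.
    """

    def __init__(self, k_neighbors: int = 5, seed: int = 0):
        self.k_neighbors = k_neighbors
        self.seed = seed

    def fit_resample(self, X, y) -> tuple[np.ndarray, np.ndarray]:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2:
            raise ValueError("SMOTE here is binary-only")
        minority = classes[np.argmin(counts)]
        majority = classes[np.argmax(counts)]
        n_min, n_maj = counts.min(), counts.max()
        if n_min == n_maj:
            return X.copy(), y.copy()
        if n_min < 2:
            raise ValueError("minority class needs >= 2 members for SMOTE")
        rng = np.random.default_rng(self.seed)
        X_min = X[y == minority]
        k = min(self.k_neighbors, n_min - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
        neigh = nn.kneighbors(X_min, return_distance=False)[:, 1:]
        n_new = n_maj - n_min
        base = rng.integers(0, n_min, size=n_new)
        pick = rng.integers(0, k, size=n_new)
        lam = rng.random(n_new)
        xi = X_min[base]
        xj = X_min[neigh[base, pick]]
        synth = xi + lam[:, None] * (xj - xi)
        X_out = np.vstack([X, synth])
        y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
        return X_out, y_out


def smote(X, y, k_neighbors: int = 5, seed: int = 0):
    """Functional wrapper over :class:`SMOTE`."""
    return SMOTE(k_neighbors=k_neighbors, seed=seed).fit_resample(X, y)
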