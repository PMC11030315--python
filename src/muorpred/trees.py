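"""Tuned tree-ensemble classifiers on descriptor tables.

Three model kinds — random forest (rf), extremely randomized trees (et),
gradient boosted trees (xgb) — tuned by randomized search over a pinned
hyperparameter space, scored by mean stratified-CV ROC AUC, and refit on
the full (optionally SMOTE-augmented) training split.  Predictions are
antagonist probabilities.

``DescriptorPipelineClassifier`` wraps the full SMILES-in protocol (2D
descriptors -> variance/collinearity filter -> optional importance-based
selection -> SMOTE -> tuned tree) as one sklearn-style estimator, the shape
used as a tri-training learner.
"""

from __future__ import annotations

import hashlib
import json
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.model_selection import RandomizedSearchCV, StratifiedKFold
from xgboost import XGBClassifier

from muorpred.features import FeatureFilter, ImportanceSelector, compute_descriptors
from muorpred.ligands import ANTAGONIST
from muorpred.metrics import optimize_threshold
from muorpred.sampling import SMOTE

RF, ET, XGB = "rf", "et", "xgb"

#: Randomized-search spaces.  The ranges are pinned for reproducibility:
#: tree count 100-1000, depth 3-20, feature subsampling 0.3-1.0, learning
#: rate 0.01-0.3 for boosted trees.
SEARCH_SPACES: dict[str, dict[str, list]] = {
    RF: {
        "n_estimators": [100, 200, 300, 500, 800, 1000],
        "max_depth": [None, 3, 5, 8, 12, 16, 20],
        "max_features": ["sqrt", "log2", 0.3, 0.5, 0.7, 1.0],
        "min_samples_leaf": [1, 2, 4, 8],
    },
    ET: {
        "n_estimators": [100, 200, 300, 500, 800, 1000],
        "max_depth": [None, 3, 5, 8, 12, 16, 20],
        "max_features": ["sqrt", "log2", 0.3, 0.5, 0.7, 1.0],
        "min_samples_leaf": [1, 2, 4, 8],
    },
    XGB: {
        "n_estimators": [100, 200, 300, 500, 800, 1000],
        "max_depth": [3, 4, 6, 8, 10, 12, 16, 20],
        "learning_rate": [0.01, 0.03, 0.1, 0.2, 0.3],
        "subsample": [0.5, 0.7, 0.9, 1.0],
        "colsample_bytree": [0.3, 0.5, 0.7, 1.0],
    },
}


def _base_estimator(kind: str, seed: int):
    if kind == RF:
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if kind == ET:
        return ExtraTreesClassifier(random_state=seed, n_jobs=1)
    if kind == XGB:
        return XGBClassifier(
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
            tree_method="hist",
        )
    raise ValueError(f"unknown tree model kind {kind!r}")


class TreeModel(BaseEstimator, ClassifierMixin):
    """A tuned tree classifier on a named-column feature table.

    Parameters
    ----------
    kind : {"rf", "et", "xgb"}
    folds : int, default 9
        Stratified-CV folds used by the randomized search.
    search_iterations : int, default 50
        Randomized-search draws (0 = skip tuning, use library defaults).
        The printed-protocol scale is 1000.
    seed : int

    Attributes
    ----------
    model_ : the fitted underlying estimator.
    columns_ : training feature names (prediction inputs are name-aligned).
    best_params_ : chosen hyperparameters (empty when tuning is skipped).
    cv_auc_ : mean CV AUC of the chosen configuration (None when skipped).
    """

    def __init__(
        self,
        kind: str = ET,
        folds: int = 9,
        search_iterations: int = 50,
        seed: int = 0,
    ):
        self.kind = kind
        self.folds = folds
        self.search_iterations = search_iterations
        self.seed = seed

    def fit(self, X, y) -> "TreeModel":
        X = pd.DataFrame(X)
        y01 = _labels01(y)
        if len(np.unique(y01)) < 2:
            raise ValueError("training data must contain both classes")
        self.columns_ = list(X.columns)
        base = _base_estimator(self.kind, self.seed)
        if self.search_iterations > 0:
            space = SEARCH_SPACES[self.kind]
            if not space:
                raise ValueError("empty hyperparameter search space")
            cv = StratifiedKFold(n_splits=self.folds, shuffle=True, random_state=self.seed)
            search = RandomizedSearchCV(
                base,
                space,
                n_iter=self.search_iterations,
                scoring="roc_auc",
                cv=cv,
                random_state=self.seed,
                n_jobs=1,
                refit=True,
            )
            search.fit(X.to_numpy(), y01)
            self.model_ = search.best_estimator_
            self.best_params_ = search.best_params_
            self.cv_auc_ = float(search.best_score_)
        else:
            self.model_ = base.fit(X.to_numpy(), y01)
            self.best_params_ = {}
            self.cv_auc_ = None
        self.classes_ = np.array([0, 1])
        return self

    def _align(self, X) -> np.ndarray:
        X = pd.DataFrame(X)
        missing = [c for c in self.columns_ if c not in X.columns]
        extra = [c for c in X.columns if c not in self.columns_]
        if missing or extra:
            raise ValueError(
                f"feature columns mismatch: missing={missing[:5]} extra={extra[:5]}"
            )
        return X[self.columns_].to_numpy()

    def predict_proba(self, X) -> np.ndarray:
        """(n, 2) array; column 1 is the antagonist probability."""
        return self.model_.predict_proba(self._align(X))

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    @property
    def feature_importances_(self) -> pd.Series:
        return pd.Series(self.model_.feature_importances_, index=self.columns_)

    def fingerprint_hash(self) -> str:
        """Digest of the fitted configuration (reproducibility check)."""
        payload = json.dumps(
            {
                "kind": self.kind,
                "seed": self.seed,
                "params": {k: str(v) for k, v in sorted(self.best_params_.items())},
                "columns": self.columns_,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()


def _labels01(y) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "SUO":
        return np.asarray([1 if v == ANTAGONIST else 0 for v in y], dtype=int)
    return y.astype(int)


def train_tree(
    kind: str,
    X,
    y,
    folds: int = 9,
    search_iterations: int = 50,
    seed: int = 0,
) -> TreeModel:
    """Functional wrapper over :class:`TreeModel`."""
    return TreeModel(kind, folds, search_iterations, seed).fit(X, y)


class DescriptorPipelineClassifier(BaseEstimator, ClassifierMixin):
    """SMILES-in tree classifier: descriptors -> filter -> [select] -> SMOTE -> tree.

    The whole feature pipeline is fit on training data only.  The decision
    threshold is optimized (max F1 of the antagonist class) on the training
    predictions and stored as ``threshold_``.
    """

    def __init__(
        self,
        kind: str = ET,
        alpha: float = 1.0,
        corr_threshold: float = 0.9,
        use_smote: bool = True,
        smote_k: int = 5,
        folds: int = 9,
        search_iterations: int = 0,
        seed: int = 0,
    ):
        self.kind = kind
        self.alpha = alpha
        self.corr_threshold = corr_threshold
        self.use_smote = use_smote
        self.smote_k = smote_k
        self.folds = folds
        self.search_iterations = search_iterations
        self.seed = seed

    def fit(self, smiles: Sequence[str], y) -> "DescriptorPipelineClassifier":
        y01 = _labels01(y)
        table = compute_descriptors(list(smiles))
        if table.attrs["excluded"]:
            keep_mask = np.array(
                [rid not in set(table.attrs["excluded"]) for rid in
                 [f"mol{i}" for i in range(len(smiles))]]
            )
            y01 = y01[keep_mask]
        self.filter_ = FeatureFilter(corr_threshold=self.corr_threshold).fit(table)
        filtered = self.filter_.transform(table)
        self.selector_ = ImportanceSelector(alpha=self.alpha, seed=self.seed).fit(
            filtered, y01
        )
        selected = self.selector_.transform(filtered)
        X, yy = selected.to_numpy(), y01
        if self.use_smote:
            X, yy = SMOTE(k_neighbors=self.smote_k, seed=self.seed).fit_resample(X, yy)
        frame = pd.DataFrame(X, columns=selected.columns)
        self.tree_ = TreeModel(
            self.kind, self.folds, self.search_iterations, self.seed
        ).fit(frame, yy)
        self.threshold_ = optimize_threshold(
            self.tree_.predict_proba(frame)[:, 1], yy
        )
        self.classes_ = np.array([0, 1])
        return self

    def _features(self, smiles: Sequence[str]) -> pd.DataFrame:
        table = compute_descriptors(list(smiles))
        if table.attrs["excluded"]:
            raise ValueError(
                f"descriptor failure for prediction molecules: {table.attrs['excluded'][:5]}"
            )
        return self.selector_.transform(self.filter_.transform(table))

    def predict_proba(self, smiles: Sequence[str]) -> np.ndarray:
        return self.tree_.predict_proba(self._features(smiles))

    def predict(self, smiles: Sequence[str]) -> np.ndarray:
        """Hard labels at the fitted F1-optimal threshold."""
        return (self.predict_proba(smiles)[:, 1] >= self.threshold_).astype(int)
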