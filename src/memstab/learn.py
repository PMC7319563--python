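"""Tree-ensemble predictors for ΔΔG regression and pathogenicity classification.

Two scikit-learn-style estimators wrap the winning algorithm families:
:class:`StabilityRegressor` (extremely randomised trees, predicting ΔΔG in
kcal/mol with negative = destabilising) and :class:`PathogenicityClassifier`
(random forest, emitting benign/pathogenic class probabilities).  Both keep a
feature-name manifest from fit and refuse prediction inputs whose columns do
not match it — name-based alignment, not positional trust.

Stability *classes* are never learned directly: they derive from the
predicted ΔΔG thresholded at ±0.4 kcal/mol (classification by regression).
"""

from __future__ import annotations

from dataclasses import dataclass

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.ensemble import ExtraTreesRegressor, RandomForestClassifier

from .dataset import ClassThresholds, classify_ddg

__all__ = [
    "FeatureMatrix",
    "StabilityRegressor",
    "PathogenicityClassifier",
    "ManifestMismatchError",
    "train_stability",
    "train_pathogenicity",
    "predict",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


class ManifestMismatchError(ValueError):
    """Prediction input whose feature names do not match the fitted manifest."""


@dataclass
class FeatureMatrix:
    """A feature table plus optional targets for one task."""

    X: pd.DataFrame
    y: pd.Series | np.ndarray | None = None
    task: str | None = None  # 'stability' | 'pathogenicity'


def _align(X, manifest: list[str]) -> np.ndarray:
    """Reorder columns by name against the fitted manifest (or verify width)."""
    if isinstance(X, pd.DataFrame):
        cols = list(X.columns)
        missing = [c for c in manifest if c not in cols]
        extra = [c for c in cols if c not in manifest]
        if missing or extra:
            raise ManifestMismatchError(
                f"feature-name manifest mismatch: missing {missing or 'none'}, "
                f"unexpected {extra or 'none'}"
            )
        return X[manifest].to_numpy(dtype=float)
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != len(manifest):
        raise ManifestMismatchError(
            f"expected {len(manifest)} features, got array of shape {arr.shape}; "
            "pass a named DataFrame for name-based alignment"
        )
    return arr


class StabilityRegressor(RegressorMixin, BaseEstimator):
    """Extra-Trees regressor for ΔΔG (kcal/mol; negative = destabilising)."""

    def __init__(
        self,
        n_estimators: int = 300,
        max_depth: int | None = None,
        random_state: int | None = 0,
        n_jobs: int = 1,
    ):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.random_state = random_state
        self.n_jobs = n_jobs

    def fit(self, X, y) -> "StabilityRegressor":
        y = np.asarray(y, dtype=float)
        if not np.all(np.isfinite(y)):
            raise ValueError("targets must be finite")
        if np.ptp(y) == 0:
            raise ValueError("degenerate targets: ΔΔG has zero variance")
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            values = X.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            self.feature_names_in_ = np.asarray(
                [f"x{i}" for i in range(values.shape[1])], dtype=object
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("feature matrix contains missing or non-finite values")
        self.n_features_in_ = values.shape[1]
        self.estimator_ = ExtraTreesRegressor(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            random_state=self.random_state,
            n_jobs=self.n_jobs,
        ).fit(values, y)
        return self

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        return self.estimator_.predict(self._align(X))

    def predict_classes(self, X, thresholds: ClassThresholds | None = None) -> np.ndarray:
        """Classification by regression: threshold predicted ΔΔG at ±0.4 kcal/mol."""
        ddg = self.predict(X)
        return np.asarray([classify_ddg(v, thresholds) for v in ddg], dtype=object)

    def _align(self, X) -> np.ndarray:
        return _align(X, list(self.feature_names_in_))

    def _check_fitted(self) -> None:
        if not hasattr(self, "estimator_"):
            raise RuntimeError("estimator is not fitted; call fit first")


class PathogenicityClassifier(ClassifierMixin, BaseEstimator):
    """Random-forest classifier for benign/pathogenic variant labels."""

    def __init__(
        self,
        n_estimators: int = 300,
        max_depth: int | None = None,
        random_state: int | None = 0,
        n_jobs: int = 1,
    ):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.random_state = random_state
        self.n_jobs = n_jobs

    def fit(self, X, y) -> "PathogenicityClassifier":
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training labels contain a single class")
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            values = X.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            self.feature_names_in_ = np.asarray(
                [f"x{i}" for i in range(values.shape[1])], dtype=object
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("feature matrix contains missing or non-finite values")
        self.n_features_in_ = values.shape[1]
        self.estimator_ = RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            random_state=self.random_state,
            n_jobs=self.n_jobs,
        ).fit(values, y)
        self.classes_ = self.estimator_.classes_
        return self

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        return self.estimator_.predict(self._align(X))

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        return self.estimator_.predict_proba(self._align(X))

    def _align(self, X) -> np.ndarray:
        return _align(X, list(self.feature_names_in_))

    def _check_fitted(self) -> None:
        if not hasattr(self, "estimator_"):
            raise RuntimeError("estimator is not fitted; call fit first")


def train_stability(
    matrix: FeatureMatrix | pd.DataFrame,
    y=None,
    hyperparams: dict | None = None,
    seed: int = 0,
) -> StabilityRegressor:
    """Fit the ΔΔG regressor (deterministic given ``seed``)."""
    X, y = _unpack(matrix, y)
    if len(X) < 20:
        raise ValueError(f"need at least 20 training rows, got {len(X)}")
    model = StabilityRegressor(random_state=seed, **(hyperparams or {}))
    return model.fit(X, y)


def train_pathogenicity(
    matrix: FeatureMatrix | pd.DataFrame,
    y=None,
    hyperparams: dict | None = None,
    seed: int = 0,
) -> PathogenicityClassifier:
    """Fit the benign/pathogenic classifier (deterministic given ``seed``)."""
    X, y = _unpack(matrix, y)
    model = PathogenicityClassifier(random_state=seed, **(hyperparams or {}))
    return model.fit(X, y)


def _unpack(matrix, y):
    if isinstance(matrix, FeatureMatrix):
        return matrix.X, matrix.y if y is None else y
    return matrix, y


def predict(model, X):
    """Batch prediction: ΔΔG array for the regressor, (labels, probabilities)
    for the classifier."""
    if isinstance(model, PathogenicityClassifier):
        proba = model.predict_proba(X)
        labels = model.classes_[np.argmax(proba, axis=1)]
        return labels, proba
    return model.predict(X)


def save_model(model, path) -> None:
    """Persist a fitted estimator with its manifest and format version."""
    model._check_fitted()
    task = "pathogenicity" if isinstance(model, PathogenicityClassifier) else "stability"
    joblib.dump(
        {
            "format_version": MODEL_FORMAT_VERSION,
            "task": task,
            "feature_names": list(model.feature_names_in_),
            "params": model.get_params(),
            "model": model,
        },
        path,
    )


def load_model(path):
    """Load a persisted estimator, refusing incompatible archive versions."""
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model archive format {version!r} is incompatible with this "
            f"package (expected {MODEL_FORMAT_VERSION})"
        )
    return payload["model"]
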