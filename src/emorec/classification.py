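"""Emotion classifier training, 10-fold evaluation and persistence.

Both classifiers the recogniser supports — an RBF-kernel support vector
machine and k-nearest neighbours — are wrapped in a pipeline that
standardises features with statistics estimated on the training data only,
because Hjorth activity (variance, amplitude² units) and mobility
(radians/sample) live on scales orders of magnitude apart.

Evaluation is stratified 10-fold cross-validation with seeded shuffling;
the report carries per-fold accuracies and a pooled confusion matrix.
Persisted models are a versioned JSON metadata file plus a joblib binary
blob holding the fitted pipeline, and a reloaded model predicts
identically to the original.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import joblib
import numpy as np
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from ._errors import InvalidArgumentError, PersistenceError
from .synth import EmotionLabel

__all__ = [
    "EmotionModel",
    "CVReport",
    "train",
    "predict",
    "cross_validate",
    "save_model",
    "load_model",
    "DEFAULT_HYPERPARAMETERS",
]

_MODEL_FORMAT_VERSION = 1

DEFAULT_HYPERPARAMETERS = {
    "svm": {"C": 1.0, "gamma": "auto", "kernel": "rbf"},  # gamma='auto' is 1/n_features
    "knn": {"n_neighbors": 5, "metric": "euclidean"},
}


def _build_pipeline(method: str, hyperparameters: dict) -> Pipeline:
    if method == "svm":
        clf = SVC(**hyperparameters)
    elif method == "knn":
        clf = KNeighborsClassifier(**hyperparameters)
    else:
        raise InvalidArgumentError(f"unknown method {method!r}; expected 'svm' or 'knn'")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


@dataclass
class EmotionModel:
    """A trained classifier plus everything needed to reproduce inference."""

    method: str
    hyperparameters: dict
    pipeline: Pipeline
    feature_family: str
    n_features: int
    classes: list[EmotionLabel]
    metadata: dict = field(default_factory=dict)


def _validate_training_input(X: np.ndarray, y: np.ndarray) -> None:
    if X.ndim != 2:
        raise InvalidArgumentError(f"feature matrix must be 2-D, got shape {X.shape}")
    if y.shape[0] != X.shape[0]:
        raise InvalidArgumentError(
            f"{X.shape[0]} feature rows but {y.shape[0]} labels"
        )
    if not np.all(np.isfinite(X)):
        bad = int(np.argwhere(~np.isfinite(X))[0][0])
        raise InvalidArgumentError(f"non-finite feature values (first bad row: {bad})")
    labels, counts = np.unique(y, return_counts=True)
    if labels.size < 2:
        raise InvalidArgumentError(
            f"training needs at least 2 classes, got only {labels.tolist()}"
        )
    thin = labels[counts < 2]
    if thin.size:
        raise InvalidArgumentError(
            f"classes {thin.tolist()} have fewer than 2 training samples"
        )


def _as_label_array(labels) -> np.ndarray:
    return np.asarray([EmotionLabel(getattr(l, "value", l)).value for l in labels])


def train(
    features: np.ndarray,
    labels,
    method: str = "svm",
    hyperparameters: dict | None = None,
    seed: int = 0,
    feature_family: str = "hjorth14",
) -> EmotionModel:
    """Fit an emotion classifier; deterministic for fixed inputs and seed."""
    X = np.asarray(features, dtype=float)
    y = _as_label_array(labels)
    _validate_training_input(X, y)
    params = dict(DEFAULT_HYPERPARAMETERS.get(method, {}))
    params.update(hyperparameters or {})
    pipeline = _build_pipeline(method, params)
    pipeline.fit(X, y)
    classes, counts = np.unique(y, return_counts=True)
    return EmotionModel(
        method=method,
        hyperparameters=params,
        pipeline=pipeline,
        feature_family=feature_family,
        n_features=X.shape[1],
        classes=[EmotionLabel(c) for c in classes],
        metadata={
            "n_per_class": {c: int(n) for c, n in zip(classes, counts)},
            "seed": seed,
            "trained_at": datetime.now(timezone.utc).isoformat(),
        },
    )


def predict(model: EmotionModel, feature_vector: np.ndarray) -> EmotionLabel:
    """Classify a single feature vector; validates the layout first."""
    v = np.asarray(feature_vector, dtype=float).ravel()
    if v.size != model.n_features:
        raise InvalidArgumentError(
            f"feature vector has length {v.size}; model "
            f"({model.feature_family}) expects {model.n_features}"
        )
    return EmotionLabel(model.pipeline.predict(v[None, :])[0])


@dataclass
class CVReport:
    """Stratified k-fold evaluation summary."""

    n_folds: int
    fold_accuracies: list[float]
    mean_accuracy: float
    confusion: np.ndarray  # classes x classes counts, pooled over folds
    classes: list[EmotionLabel]
    method: str
    seed: int

    def to_dict(self) -> dict:
        return {
            "n_folds": self.n_folds,
            "fold_accuracies": self.fold_accuracies,
            "mean_accuracy": self.mean_accuracy,
            "confusion": self.confusion.tolist(),
            "classes": [c.value for c in self.classes],
            "method": self.method,
            "seed": self.seed,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")


def cross_validate(
    features: np.ndarray,
    labels,
    method: str = "svm",
    hyperparameters: dict | None = None,
    k_folds: int = 10,
    seed: int = 0,
) -> CVReport:
    """Stratified k-fold cross-validation with seeded shuffling.

    Folds are disjoint, cover every sample, and differ in size by at most
    one.  The confusion matrix pools the held-out predictions of all
    folds, so its entries sum to ``n_samples``.
    """
    X = np.asarray(features, dtype=float)
    y = _as_label_array(labels)
    _validate_training_input(X, y)
    if X.shape[0] < k_folds:
        raise InvalidArgumentError(
            f"{X.shape[0]} samples cannot be split into {k_folds} folds"
        )
    params = dict(DEFAULT_HYPERPARAMETERS.get(method, {}))
    params.update(hyperparameters or {})
    class_values = sorted(np.unique(y))

    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    fold_acc: list[float] = []
    pooled = np.zeros((len(class_values), len(class_values)), dtype=int)
    for train_idx, test_idx in skf.split(X, y):
        pipeline = _build_pipeline(method, params)
        pipeline.fit(X[train_idx], y[train_idx])
        pred = pipeline.predict(X[test_idx])
        fold_acc.append(float(np.mean(pred == y[test_idx])))
        pooled += confusion_matrix(y[test_idx], pred, labels=class_values)
    return CVReport(
        n_folds=k_folds,
        fold_accuracies=fold_acc,
        mean_accuracy=float(np.mean(fold_acc)),
        confusion=pooled,
        classes=[EmotionLabel(c) for c in class_values],
        method=method,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Persistence: <path> is JSON metadata; <path>.bin is the joblib blob.


def save_model(model: EmotionModel, path: str | Path) -> None:
    path = Path(path)
    blob = path.with_suffix(path.suffix + ".bin")
    joblib.dump(model.pipeline, blob)
    meta = {
        "format_version": _MODEL_FORMAT_VERSION,
        "method": model.method,
        "hyperparameters": model.hyperparameters,
        "feature_family": model.feature_family,
        "n_features": model.n_features,
        "classes": [c.value for c in model.classes],
        "metadata": model.metadata,
        "blob": blob.name,
    }
    path.write_text(json.dumps(meta, indent=2), encoding="utf-8")


def load_model(path: str | Path) -> EmotionModel:
    path = Path(path)
    try:
        meta = json.loads(path.read_text(encoding="utf-8"))
    except (OSError, json.JSONDecodeError) as exc:
        raise PersistenceError(f"cannot read model metadata {path}: {exc}") from exc
    version = meta.get("format_version")
    if version != _MODEL_FORMAT_VERSION:
        raise PersistenceError(
            f"model format version {version!r} not supported "
            f"(expected {_MODEL_FORMAT_VERSION})"
        )
    pipeline = joblib.load(path.parent / meta["blob"])
    return EmotionModel(
        method=meta["method"],
        hyperparameters=meta["hyperparameters"],
        pipeline=pipeline,
        feature_family=meta["feature_family"],
        n_features=meta["n_features"],
        classes=[EmotionLabel(c) for c in meta["classes"]],
        metadata=meta["metadata"],
    )
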