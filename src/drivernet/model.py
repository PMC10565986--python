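"""Random-forest driver/passenger classification on combined features.

The classifier consumes the (91 + C)-column design matrix from
:mod:`drivernet.dataset` — per-variant sequence/structure features joined
with the gene's graph embedding — and scores each variant with the
probability of being a driver.  Hyperparameters are tuned by exhaustive grid
search with stratified 3-fold inner cross-validation, maximizing ROC-AUC,
then refit on all rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold

from .dataset import FeatureMatrix

__all__ = [
    "GridSpec",
    "ClassifierModel",
    "SchemaError",
    "default_grid",
    "train_classifier",
    "predict_scores",
    "save_model",
    "load_model",
]

_FORMAT_VERSION = 1


class SchemaError(ValueError):
    """Prediction-time feature schema mismatch."""


@dataclass(frozen=True)
class GridSpec:
    """Candidate hyperparameter values for the inner grid search."""

    n_estimators: tuple[int, ...] = (100, 300, 500)
    max_depth: tuple[int | None, ...] = (None, 10, 20)
    max_features: tuple = ("sqrt", 0.3)

    def __post_init__(self) -> None:
        if not (self.n_estimators and self.max_depth and self.max_features):
            raise ValueError("grid must be non-empty in every dimension")

    def to_param_grid(self) -> dict:
        return {
            "n_estimators": list(self.n_estimators),
            "max_depth": list(self.max_depth),
            "max_features": list(self.max_features),
        }


def default_grid() -> GridSpec:
    return GridSpec()


def small_grid() -> GridSpec:
    """Single-combination grid for harness loops where tuning is not the point."""
    return GridSpec(n_estimators=(300,), max_depth=(None,), max_features=("sqrt",))


@dataclass
class ClassifierModel:
    estimator: RandomForestClassifier
    feature_names: tuple[str, ...]
    best_params: dict
    inner_cv_score: float
    seed: int
    imputation_means: pd.Series | None = None


def _extract_xy(X, y=None):
    if isinstance(X, FeatureMatrix):
        return X.X, X.y, X.imputation_means
    if y is None:
        raise ValueError("y is required when X is not a FeatureMatrix")
    return pd.DataFrame(X), np.asarray(y), None


def train_classifier(X, grid: GridSpec | None = None, seed: int = 0, y=None) -> ClassifierModel:
    """Grid-searched random forest; reproducible given the seed."""
    Xdf, yv, means = _extract_xy(X, y)
    if Xdf.isna().any().any():
        raise ValueError("design matrix contains missing values; impute first")
    classes = np.unique(yv)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    grid = grid or default_grid()
    search = GridSearchCV(
        RandomForestClassifier(random_state=seed),
        grid.to_param_grid(),
        scoring="roc_auc",
        cv=StratifiedKFold(n_splits=3, shuffle=True, random_state=seed),
        refit=True,
        n_jobs=1,
    )
    search.fit(Xdf.to_numpy(), yv)
    return ClassifierModel(
        estimator=search.best_estimator_,
        feature_names=tuple(Xdf.columns),
        best_params=dict(search.best_params_),
        inner_cv_score=float(search.best_score_),
        seed=seed,
        imputation_means=means,
    )


def predict_scores(model: ClassifierModel, X) -> np.ndarray:
    """Driver probability per row; columns aligned to the model by name."""
    Xdf = X.X if isinstance(X, FeatureMatrix) else pd.DataFrame(X)
    missing = [c for c in model.feature_names if c not in Xdf.columns]
    if missing:
        raise SchemaError(f"missing feature column(s): {missing[:10]}")
    Xdf = Xdf[list(model.feature_names)]
    proba = model.estimator.predict_proba(Xdf.to_numpy())
    pos = list(model.estimator.classes_).index(1)
    return proba[:, pos]


def save_model(model: ClassifierModel, path: str | Path) -> None:
    """Persist the model plus a JSON sidecar of its schema and settings."""
    path = Path(path)
    joblib.dump({"format_version": _FORMAT_VERSION, "model": model}, path)
    sidecar = {
        "format_version": _FORMAT_VERSION,
        "feature_names": list(model.feature_names),
        "best_params": model.best_params,
        "seed": model.seed,
        "inner_cv_score": model.inner_cv_score,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> ClassifierModel:
    try:
        payload = joblib.load(path)
    except Exception as exc:  # corrupted / not a joblib file
        raise ValueError(f"cannot load model from {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ValueError(f"{path} is not a drivernet model file")
    if payload["format_version"] != _FORMAT_VERSION:
        raise ValueError(
            f"model format version {payload['format_version']} unsupported "
            f"(expected {_FORMAT_VERSION})"
        )
    return payload["model"]
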