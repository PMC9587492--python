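"""Uniform train/predict adapters over the four classifier families.

The GA engine is classifier-agnostic: it hands a :class:`ClassifierSpec` and a
complete design matrix to :func:`train` and gets back a :class:`FittedModel`
whose :func:`predict` enforces the exact feature set and order used at fit
time.  Logistic regression and the RBF-kernel SVM are wrapped in a
standardisation pipeline (scaling parameters learned on the training data
only); tree models consume raw codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

CLASSIFIER_KINDS = ("logistic_regression", "svm", "decision_tree", "random_forest")

_SCALED_KINDS = {"logistic_regression", "svm"}


@dataclass(frozen=True)
class ClassifierSpec:
    """One of the four families plus hyperparameter overrides and a seed."""

    kind: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"kind must be one of {CLASSIFIER_KINDS}, got {self.kind!r}")
        object.__setattr__(self, "hyperparameters", dict(self.hyperparameters))

    def build(self):
        """Fresh, unfitted scikit-learn estimator for this spec."""
        params = dict(self.hyperparameters)
        if self.kind == "logistic_regression":
            model = LogisticRegression(max_iter=2000, **params)
        elif self.kind == "svm":
            model = SVC(kernel=params.pop("kernel", "rbf"), random_state=self.seed, **params)
        elif self.kind == "decision_tree":
            model = DecisionTreeClassifier(
                criterion=params.pop("criterion", "entropy"), random_state=self.seed, **params
            )
        else:  # random_forest
            model = RandomForestClassifier(
                n_estimators=params.pop("n_estimators", 100), random_state=self.seed, **params
            )
        if self.kind in _SCALED_KINDS:
            return Pipeline([("scale", StandardScaler()), ("model", model)])
        return model

    def to_dict(self) -> dict:
        return {"kind": self.kind, "hyperparameters": dict(self.hyperparameters), "seed": self.seed}

    @classmethod
    def from_dict(cls, payload: Mapping) -> "ClassifierSpec":
        return cls(
            kind=payload["kind"],
            hyperparameters=payload.get("hyperparameters", {}),
            seed=int(payload.get("seed", 0)),
        )


@dataclass
class FittedModel:
    """A fitted estimator bound to the exact feature list it was trained on."""

    spec: ClassifierSpec
    feature_names_used: tuple[str, ...]
    estimator: object

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return predict(self, X)


def _as_matrix(X: pd.DataFrame | np.ndarray) -> np.ndarray:
    return X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)


def train(spec: ClassifierSpec, X: pd.DataFrame, y) -> FittedModel:
    """Fit *spec* on a complete design matrix; deterministic given ``spec.seed``."""
    if X.shape[1] == 0:
        raise ValueError("training requires at least one feature")
    matrix = _as_matrix(X)
    if np.isnan(matrix).any():
        raise ValueError("training matrix contains missing values; impute first")
    y = np.asarray(y, dtype=int)
    if len(y) != len(matrix):
        raise ValueError("X and y have different lengths")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("single-class training set")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 training records")
    estimator = spec.build()
    estimator.fit(matrix, y)
    names = tuple(X.columns) if isinstance(X, pd.DataFrame) else tuple(
        f"x{i}" for i in range(matrix.shape[1])
    )
    return FittedModel(spec=spec, feature_names_used=names, estimator=estimator)


def predict(model: FittedModel, X: pd.DataFrame) -> np.ndarray:
    """Predict 0/1 labels; refuses inputs whose columns differ from training."""
    if isinstance(X, pd.DataFrame):
        got = tuple(X.columns)
        if got != model.feature_names_used:
            missing = [n for n in model.feature_names_used if n not in got]
            extra = [n for n in got if n not in model.feature_names_used]
            detail = (
                f"missing={missing}, extra={extra}"
                if missing or extra
                else f"column order differs: expected {list(model.feature_names_used)}"
            )
            raise ValueError(f"feature columns do not match the fitted model ({detail})")
    matrix = _as_matrix(X)
    if matrix.shape[0] == 0:
        return np.empty(0, dtype=int)
    if matrix.shape[1] != len(model.feature_names_used):
        raise ValueError(
            f"expected {len(model.feature_names_used)} feature columns, got {matrix.shape[1]}"
        )
    return np.asarray(model.estimator.predict(matrix), dtype=int)
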