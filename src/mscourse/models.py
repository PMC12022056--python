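"""Underlying probabilistic classifiers for the RRMS/SPMS visit labels.

Four model families are supported; the default hyperparameters are the
tuned values used throughout the pipeline (random forest: 150 trees, Gini,
min 5 samples per leaf; gradient boosting: 50 estimators, min split 2,
friedman_mse, exponential loss; RBF-SVM: gamma 1e-4, C 1).  Logistic
regression keeps scikit-learn defaults.  Grid search is intentionally out of
scope -- defaults are overridable through :class:`ModelSpec`.

Cross-validation is grouped by patient id so that visits from one patient
never straddle folds, which would leak longitudinal information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score
from sklearn.model_selection import GroupKFold
from sklearn.svm import SVC

from .simulate import RRMS, SPMS, ConfigurationError

MODEL_KINDS = ("logistic_regression", "svm_rbf", "gradient_boosting", "random_forest")

_DEFAULTS: dict[str, dict] = {
    "random_forest": dict(n_estimators=150, criterion="gini", min_samples_leaf=5),
    "gradient_boosting": dict(n_estimators=50, min_samples_split=2,
                              criterion="friedman_mse", loss="exponential"),
    "svm_rbf": dict(gamma=1e-4, C=1.0),
    "logistic_regression": dict(max_iter=2000),
}


@dataclass(frozen=True)
class ModelSpec:
    kind: str = "random_forest"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ConfigurationError(
                f"unknown model kind {self.kind!r}; choose from {MODEL_KINDS}")

    def build(self):
        params = {**_DEFAULTS[self.kind], **self.hyperparameters}
        if self.kind == "random_forest":
            return RandomForestClassifier(random_state=self.seed, **params)
        if self.kind == "gradient_boosting":
            return GradientBoostingClassifier(random_state=self.seed, **params)
        if self.kind == "svm_rbf":
            # probability=True fits an internal score-to-probability
            # calibration on training folds (Platt scaling)
            return SVC(kernel="rbf", probability=True, random_state=self.seed, **params)
        return LogisticRegression(random_state=self.seed, **params)


class SchemaMismatchError(ValueError):
    """Feature matrix does not match the schema the model was trained on."""


@dataclass
class ProbabilisticClassifier:
    """A fitted binary classifier with a fixed (RRMS, SPMS) class order.

    ``predict_proba`` returns columns in that order regardless of the label
    encoding seen at fit time, and refuses inputs whose schema fingerprint
    differs from the training fingerprint.
    """

    spec: ModelSpec
    estimator: object
    schema_fingerprint: Optional[str]
    classes: tuple[str, str] = (RRMS, SPMS)

    def _check(self, X: np.ndarray, fingerprint: Optional[str]) -> np.ndarray:
        if (fingerprint is not None and self.schema_fingerprint is not None
                and fingerprint != self.schema_fingerprint):
            raise SchemaMismatchError(
                f"feature schema fingerprint {fingerprint} does not match the "
                f"model's training fingerprint {self.schema_fingerprint}")
        X = np.asarray(X, dtype=float)
        return X.reshape(1, -1) if X.ndim == 1 else X

    def predict_proba(self, X: np.ndarray, fingerprint: Optional[str] = None) -> np.ndarray:
        X = self._check(X, fingerprint)
        proba = self.estimator.predict_proba(X)
        order = np.argsort(self.estimator.classes_)  # 0 (RRMS) before 1 (SPMS)
        proba = proba[:, order]
        if not np.allclose(proba.sum(axis=1), 1.0, atol=1e-9):
            raise AssertionError("predicted probabilities do not sum to 1")
        return proba

    def predict(self, X: np.ndarray, fingerprint: Optional[str] = None) -> np.ndarray:
        return self.predict_proba(X, fingerprint).argmax(axis=1)


def train(spec: ModelSpec, X: np.ndarray, y: np.ndarray,
          schema_fingerprint: Optional[str] = None) -> ProbabilisticClassifier:
    """Fit a classifier; ``y`` uses 0 for RRMS and 1 for SPMS."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"X has {X.shape[0]} rows but y has {y.shape[0]}")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class; "
                         "downstream calibration needs both RRMS and SPMS")
    est = spec.build()
    est.fit(X, y)
    return ProbabilisticClassifier(spec, est, schema_fingerprint)


def cross_validate_f1(spec: ModelSpec, X: np.ndarray, y: np.ndarray,
                      groups: np.ndarray, k: int = 10) -> tuple[float, float, np.ndarray]:
    """Grouped k-fold macro-F1: returns (mean, sd, per-fold scores).

    Folds are formed over patient ids so no patient contributes visits to
    more than one fold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    groups = np.asarray(groups)
    n_groups = len(np.unique(groups))
    if k > n_groups:
        raise ValueError(f"k={k} exceeds the number of patient groups ({n_groups})")
    scores = []
    for train_idx, test_idx in GroupKFold(n_splits=k).split(X, y, groups):
        est = spec.build()
        est.fit(X[train_idx], y[train_idx])
        pred = est.predict(X[test_idx])
        scores.append(f1_score(y[test_idx], pred, average="macro"))
    scores = np.asarray(scores)
    return float(scores.mean()), float(scores.std(ddof=1)), scores
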