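"""Classical classifiers over utterance-level acoustic features.

Four fixed-hyperparameter models: a linear SVM (C=1), linear discriminant
analysis, k-nearest neighbors (k=5, Euclidean), and a random forest
(100 trees, Gini).  Features are z-scored with statistics fitted on the
training partition only (the forest, being scale-invariant, skips the
scaler).  Scores for ROC analysis come from the decision function where
one exists and from the positive-class probability otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import UtteranceFeatures

__all__ = ["BaselineSpec", "BASELINE_KINDS", "fit_baseline",
           "predict_baseline", "features_to_matrix"]

BASELINE_KINDS = ("svm_linear", "lda", "knn", "rf")


@dataclass(frozen=True)
class BaselineSpec:
    kind: str = "rf"
    seed: int = 0
    standardize: bool = True
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in BASELINE_KINDS:
            raise ValueError(f"unknown baseline kind {self.kind!r}")


def _make_estimator(spec: BaselineSpec):
    if spec.kind == "svm_linear":
        est = SVC(kernel="linear", C=1.0, **spec.params)
    elif spec.kind == "lda":
        est = LinearDiscriminantAnalysis(**spec.params)
    elif spec.kind == "knn":
        est = KNeighborsClassifier(n_neighbors=5, metric="euclidean",
                                   **spec.params)
    else:
        est = RandomForestClassifier(n_estimators=100, criterion="gini",
                                     random_state=spec.seed, **spec.params)
    if spec.standardize and spec.kind != "rf":
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    return est


def features_to_matrix(features: list[UtteranceFeatures]
                       ) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([f.vector for f in features])
    y = np.array([f.label for f in features], dtype=int)
    return X, y


def fit_baseline(spec: BaselineSpec, X: np.ndarray, y: np.ndarray):
    """Fit one baseline; raises on a single-class training set."""
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    if len(X) != len(y):
        raise ValueError("feature/label length mismatch")
    est = _make_estimator(spec)
    est.fit(X, y)
    return est


def predict_baseline(est, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels plus a score usable for ROC sweeps."""
    labels = est.predict(X)
    if hasattr(est, "decision_function"):
        scores = est.decision_function(X)
    else:
        scores = est.predict_proba(X)[:, 1]
    return labels, scores
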