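"""Uniform train/predict interface over six classifier families.

Families: random_forest (default, 500 trees), naive_bayes (Gaussian),
svm (RBF kernel with probability scores), gradient_boosting (XGBoost
backend, sklearn fallback), logistic_regression, decision_tree.
Predictions expose a positive-class score in [0, 1]; the decision threshold
is 0.5.  A trained model remembers the exact feature-name ordering used at
fit time and refuses inputs that deviate from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import joblib
import numpy as np

from .encoder import FeatureMatrix

FAMILIES = (
    "random_forest",
    "naive_bayes",
    "svm",
    "gradient_boosting",
    "logistic_regression",
    "decision_tree",
)

MODEL_FORMAT_VERSION = 1
DECISION_THRESHOLD = 0.5


@dataclass(frozen=True)
class ClassifierSpec:
    family: str = "random_forest"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 42

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown classifier family {self.family!r}; choose from {FAMILIES}")


def _build_estimator(spec: ClassifierSpec):
    hp = dict(spec.hyperparameters)
    if spec.family == "random_forest":
        from sklearn.ensemble import RandomForestClassifier

        hp.setdefault("n_estimators", 500)
        return RandomForestClassifier(random_state=spec.seed, n_jobs=1, **hp)
    if spec.family == "naive_bayes":
        from sklearn.naive_bayes import GaussianNB

        return GaussianNB(**hp)
    if spec.family == "svm":
        from sklearn.svm import SVC

        hp.setdefault("kernel", "rbf")
        hp.setdefault("probability", True)
        return SVC(random_state=spec.seed, **hp)
    if spec.family == "gradient_boosting":
        backend = hp.pop("backend", "xgboost")
        if backend == "xgboost":
            try:
                from xgboost import XGBClassifier
            except ImportError:  # pragma: no cover
                backend = "sklearn"
            else:
                hp.setdefault("n_estimators", 200)
                hp.setdefault("eval_metric", "logloss")
                return XGBClassifier(random_state=spec.seed, n_jobs=1, **hp)
        from sklearn.ensemble import GradientBoostingClassifier

        return GradientBoostingClassifier(random_state=spec.seed, **hp)
    if spec.family == "logistic_regression":
        from sklearn.linear_model import LogisticRegression

        hp.setdefault("max_iter", 2000)
        return LogisticRegression(random_state=spec.seed, **hp)
    if spec.family == "decision_tree":
        from sklearn.tree import DecisionTreeClassifier

        return DecisionTreeClassifier(random_state=spec.seed, **hp)
    raise ValueError(f"unknown family {spec.family!r}")  # unreachable after spec validation


@dataclass
class TrainedModel:
    spec: ClassifierSpec
    feature_names: list[str]
    estimator: Any
    meta: dict = field(default_factory=dict)


def train(matrix: FeatureMatrix, spec: ClassifierSpec | None = None) -> TrainedModel:
    """Fit one classifier on a labelled feature matrix (deterministic by seed)."""
    spec = spec or ClassifierSpec()
    y = np.asarray(matrix.labels, dtype=int)
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError(f"training requires both binary classes 0 and 1; got classes {classes}")
    est = _build_estimator(spec)
    est.fit(matrix.X, y)
    meta = {
        "n_samples": {"0": int(np.sum(y == 0)), "1": int(np.sum(y == 1))},
        "trained_at": datetime.now(timezone.utc).isoformat(),
    }
    return TrainedModel(spec=spec, feature_names=list(matrix.feature_names), estimator=est, meta=meta)


def predict(model: TrainedModel, matrix: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Predict labels and positive-class scores; label = 1 iff score >= 0.5.

    The matrix columns must match the model's fit-time feature names exactly
    (same names, same order); the first mismatch is named in the error.
    """
    if list(matrix.feature_names) != model.feature_names:
        if len(matrix.feature_names) != len(model.feature_names):
            raise ValueError(
                f"feature contract mismatch: model expects {len(model.feature_names)} "
                f"columns, input has {len(matrix.feature_names)}"
            )
        for i, (got, want) in enumerate(zip(matrix.feature_names, model.feature_names)):
            if got != want:
                raise ValueError(
                    f"feature contract mismatch at column {i}: expected {want!r}, got {got!r}"
                )
    proba = model.estimator.predict_proba(matrix.X)
    pos_col = int(np.flatnonzero(model.estimator.classes_ == 1)[0])
    scores = proba[:, pos_col]
    labels = (scores >= DECISION_THRESHOLD).astype(int)
    return labels, scores


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize a trained model with format version and feature contract."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "spec": model.spec,
        "feature_names": model.feature_names,
        "estimator": model.estimator,
        "meta": model.meta,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> TrainedModel:
    """Load a model saved by :func:`save_model`; refuses version mismatches."""
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ValueError(f"cannot load model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ValueError(f"{path} is not an aquapred model file")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format version {payload['format_version']} unsupported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    return TrainedModel(
        spec=payload["spec"],
        feature_names=payload["feature_names"],
        estimator=payload["estimator"],
        meta=payload.get("meta", {}),
    )
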