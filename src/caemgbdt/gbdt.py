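"""Gradient-boosted decision-tree subtype classifier and evaluation metrics.

The boosting engine is scikit-learn's ``GradientBoostingClassifier``
(classic forward-stagewise additive trees on the multinomial/binomial
log-loss), configured to the method's fixed hyperparameters: learning rate
0.1, at most 300 stages, depth-3 trees, at least 5 samples per leaf and per
split, stage subsampling 0.8. Multi-class problems train one tree per class
per stage (one-vs-all), so K classes and M stages give M*K trees; per-class
scores are softmax-normalized into probabilities. Optional early stopping
monitors a held-out 15% validation slice with patience 10.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support
from sklearn.utils.validation import check_is_fitted

from .features import AssembledFeatures

MAX_ESTIMATORS = 300


def logloss(y: Sequence[float], p: Sequence[float], eps: float = 1e-15) -> float:
    """Binary cross-entropy  -(1/N) * sum[y log p + (1-y) log(1-p)].

    Probabilities are clipped to ``[eps, 1-eps]`` before taking logs.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {p.shape}")
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def multiclass_logloss(y: np.ndarray, proba: np.ndarray, eps: float = 1e-15) -> float:
    """Multinomial log-loss for integer labels against a probability matrix."""
    proba = np.clip(np.asarray(proba, dtype=float), eps, 1.0 - eps)
    return float(-np.mean(np.log(proba[np.arange(len(y)), np.asarray(y, dtype=int)])))


@dataclass(frozen=True)
class GBDTConfig:
    """The classifier's fixed hyperparameters plus seed and stopping policy."""

    learning_rate: float = 0.1
    n_estimators: int = 300
    max_depth: int = 3
    min_samples_leaf: int = 5
    min_samples_split: int = 5
    subsample: float = 0.8
    loss: str = "deviance"
    seed: int = 0
    #: (validation fraction, patience) or None to disable early stopping
    early_stopping: Optional[Tuple[float, int]] = None

    def __post_init__(self):
        if not 0 < self.learning_rate <= 1:
            raise ValueError("learning_rate must lie in (0, 1]")
        if not 0 < self.subsample <= 1:
            raise ValueError("subsample must lie in (0, 1]")
        if self.n_estimators > MAX_ESTIMATORS:
            raise ValueError(f"n_estimators is capped at {MAX_ESTIMATORS}")
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if self.loss != "deviance":
            raise ValueError("only the 'deviance' (log-loss) objective is supported")


def _as_matrix(features: Union[AssembledFeatures, np.ndarray]) -> np.ndarray:
    return features.values if isinstance(features, AssembledFeatures) else np.asarray(features)


class GBDTSubtypeClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn estimator wrapping the configured boosting ensemble.

    Defaults reproduce the method's fixed configuration; ``early_stopping``
    switches on validation-monitored stopping (fraction 0.15, patience 10).
    """

    def __init__(self, learning_rate: float = 0.1, n_estimators: int = 300,
                 max_depth: int = 3, min_samples_leaf: int = 5,
                 min_samples_split: int = 5, subsample: float = 0.8,
                 early_stopping: bool = False, validation_fraction: float = 0.15,
                 patience: int = 10, random_state: int = 0):
        self.learning_rate = learning_rate
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.min_samples_split = min_samples_split
        self.subsample = subsample
        self.early_stopping = early_stopping
        self.validation_fraction = validation_fraction
        self.patience = patience
        self.random_state = random_state

    def _config(self) -> GBDTConfig:
        return GBDTConfig(
            learning_rate=self.learning_rate, n_estimators=self.n_estimators,
            max_depth=self.max_depth, min_samples_leaf=self.min_samples_leaf,
            min_samples_split=self.min_samples_split, subsample=self.subsample,
            seed=self.random_state,
            early_stopping=(self.validation_fraction, self.patience)
            if self.early_stopping else None,
        )

    def fit(self, X, y):
        cfg = self._config()  # validates ranges and the 300-tree cap
        X = _as_matrix(X)
        y = np.asarray(y)
        classes, y_codes = np.unique(y, return_inverse=True)
        if classes.size < 2:
            raise ValueError("labels contain a single class; nothing to boost")
        counts = np.bincount(y_codes)
        small = classes[counts < self.min_samples_leaf]
        if small.size:
            warnings.warn(f"classes with fewer than min_samples_leaf samples: "
                          f"{small.tolist()}")
        kwargs = dict(
            loss="log_loss", learning_rate=cfg.learning_rate,
            n_estimators=cfg.n_estimators, max_depth=cfg.max_depth,
            min_samples_leaf=cfg.min_samples_leaf,
            min_samples_split=cfg.min_samples_split,
            subsample=cfg.subsample, random_state=cfg.seed,
        )
        if cfg.early_stopping is not None:
            frac, patience = cfg.early_stopping
            kwargs.update(validation_fraction=frac, n_iter_no_change=patience)
        model = GradientBoostingClassifier(**kwargs)
        model.fit(X, y_codes)
        self.model_ = model
        self.classes_ = classes
        self.config_ = cfg
        self.n_features_in_ = X.shape[1]
        self.n_stages_ = model.estimators_.shape[0]
        self.total_trees_ = int(model.estimators_.size)
        self.staged_train_loss_ = [
            multiclass_logloss(y_codes, proba)
            for proba in model.staged_predict_proba(X)
        ]
        return self

    def _check_width(self, X: np.ndarray) -> np.ndarray:
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature layout mismatch: model was trained on "
                f"{self.n_features_in_} columns, got {X.shape[1]}")
        return X

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(self._check_width(_as_matrix(X)))

    def predict(self, X):
        check_is_fitted(self, "model_")
        codes = self.model_.predict(self._check_width(_as_matrix(X)))
        return self.classes_[codes]

    def save(self, path: str) -> None:
        import joblib

        joblib.dump(self, path)
        with open(str(path) + ".json", "w") as fh:
            json.dump({"config": self.config_.__dict__, "seed": self.random_state},
                      fh, indent=1, default=str)


# --- metrics -----------------------------------------------------------

@dataclass
class MetricsReport:
    """Accuracy plus macro-averaged precision/recall/F1, as percentages."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    per_class: pd.DataFrame
    confusion: np.ndarray
    class_names: List[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "accuracy": round(self.accuracy, 1),
            "precision": round(self.precision, 1),
            "recall": round(self.recall, 1),
            "f1": round(self.f1, 1),
            "per_class": {
                str(row.Index): {"precision": round(row.precision, 1),
                                 "recall": round(row.recall, 1),
                                 "f1": round(row.f1, 1),
                                 "support": int(row.support)}
                for row in self.per_class.itertuples()
            },
            "confusion": self.confusion.tolist(),
            "class_names": list(self.class_names),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.as_dict(), **kwargs)

    def format_table(self) -> str:
        head = (f"accuracy {self.accuracy:5.1f}  precision {self.precision:5.1f}  "
                f"recall {self.recall:5.1f}  F1 {self.f1:5.1f}  (macro, %)")
        return head + "\n" + self.per_class.round(1).to_string()


def evaluate(y_true, y_pred, class_names: Optional[Sequence[str]] = None) -> MetricsReport:
    """Accuracy and one-vs-rest macro precision/recall/F1 (percent).

    Per class: precision and recall from the one-vs-rest confusion counts,
    F1 their harmonic mean; macro values are unweighted class means.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred differ in length")
    if class_names is None:
        class_names = [str(c) for c in np.unique(np.concatenate([y_true, y_pred]))]
    labels = np.arange(len(class_names)) if np.issubdtype(y_true.dtype, np.integer) \
        else np.asarray(class_names)
    unknown = set(np.unique(y_pred)) - set(labels.tolist())
    if unknown:
        raise ValueError(f"predicted classes not in class_names: {sorted(unknown)}")
    acc = float(np.mean(y_true == y_pred))
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average=None, zero_division=0)
    per_class = pd.DataFrame(
        {"precision": prec * 100, "recall": rec * 100, "f1": f1 * 100,
         "support": support},
        index=list(class_names))
    conf = _sk_confusion(y_true, y_pred, labels=labels)
    return MetricsReport(
        accuracy=acc * 100, precision=float(prec.mean() * 100),
        recall=float(rec.mean() * 100), f1=float(f1.mean() * 100),
        per_class=per_class, confusion=conf, class_names=list(class_names))


# --- thin functional wrappers ------------------------------------------

def fit_gbdt(features: Union[AssembledFeatures, np.ndarray], labels,
             config: Optional[GBDTConfig] = None) -> GBDTSubtypeClassifier:
    cfg = config or GBDTConfig()
    est = GBDTSubtypeClassifier(
        learning_rate=cfg.learning_rate, n_estimators=cfg.n_estimators,
        max_depth=cfg.max_depth, min_samples_leaf=cfg.min_samples_leaf,
        min_samples_split=cfg.min_samples_split, subsample=cfg.subsample,
        early_stopping=cfg.early_stopping is not None,
        validation_fraction=cfg.early_stopping[0] if cfg.early_stopping else 0.15,
        patience=cfg.early_stopping[1] if cfg.early_stopping else 10,
        random_state=cfg.seed)
    y = labels.labels if hasattr(labels, "labels") else labels
    return est.fit(features, y)


def predict(model: GBDTSubtypeClassifier,
            features: Union[AssembledFeatures, np.ndarray]):
    """Predicted labels and the per-class probability matrix."""
    return model.predict(features), model.predict_proba(features)
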