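"""Classifier construction, class weighting, grid search with stratified
k-fold CV, and prediction with an applicability-domain distance.

Model families: random forest, SVM with RBF kernel, SVM with polynomial
kernel (scikit-learn estimators under the hood).  Class weights follow
``n_samples / (n_classes * class_count)``.  Every prediction carries the
Mahalanobis distance of the query fingerprint to the training data (mean and
covariance pseudo-inverse frozen into the model artifact) as an
applicability-domain measure.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .evaluation import MetricsReport, confusion, metrics, roc_auc
from .exceptions import ConfigurationError, InputError, UndefinedMetricError

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "ClassWeights",
    "PredictionResult",
    "ModelArtifact",
    "GridSearchResult",
    "class_weights",
    "default_grids",
    "grid_search_cv",
    "train",
    "predict",
    "save_model",
    "load_model",
]

_FAMILIES = ("random_forest", "svm_rbf", "svm_poly")


@dataclass(frozen=True)
class ModelSpec:
    family: str
    hyperparameters: Tuple[Tuple[str, object], ...]
    seed: int = 0

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ConfigurationError(f"family must be one of {_FAMILIES}")

    @property
    def params(self) -> Dict[str, object]:
        return dict(self.hyperparameters)

    @classmethod
    def make(cls, family: str, seed: int = 0, **params) -> "ModelSpec":
        return cls(family=family,
                   hyperparameters=tuple(sorted(params.items())), seed=seed)


@dataclass(frozen=True)
class ClassWeights:
    weight_active: float
    weight_inactive: float

    def as_dict(self) -> Dict[int, float]:
        return {1: self.weight_active, 0: self.weight_inactive}


@dataclass
class PredictionResult:
    compound_id: str
    predicted_label: int
    probability_active: float
    ad_distance: float


@dataclass
class ModelArtifact:
    """Everything needed to reproduce predictions: spec, learner, AD statistics."""

    spec: ModelSpec
    model: object
    train_mean: np.ndarray
    cov_pinv: np.ndarray
    n_features: int
    schema_json: Optional[str] = None
    ad_reference: str = "all"  # "all" or "active"


@dataclass
class GridSearchResult:
    best_spec: ModelSpec
    best_fold_reports: List[MetricsReport]
    cv_table: List[Dict[str, object]]  # one row per configuration


def class_weights(labels: Sequence[int]) -> ClassWeights:
    """``n_samples / (n_classes * class_count)`` per class."""
    y = np.asarray(labels, dtype=int)
    n_active = int((y == 1).sum())
    n_inactive = int((y == 0).sum())
    if n_active == 0 or n_inactive == 0:
        raise InputError("both classes must be present to compute weights")
    n = n_active + n_inactive
    return ClassWeights(
        weight_active=n / (2 * n_active),
        weight_inactive=n / (2 * n_inactive),
    )


def default_grids(family: str, dataset_kind: str) -> List[Dict[str, object]]:
    """Reference hyperparameter grids per model family and dataset balance."""
    if family not in _FAMILIES or dataset_kind not in ("imbalanced", "balanced"):
        raise ConfigurationError(
            f"unknown combination ({family!r}, {dataset_kind!r})")

    def expand(**axes) -> List[Dict[str, object]]:
        keys = list(axes)
        return [dict(zip(keys, combo))
                for combo in itertools.product(*axes.values())]

    if family == "random_forest":
        if dataset_kind == "imbalanced":
            return expand(
                max_depth=list(range(200, 1000, 100)),
                n_estimators=list(range(100, 1100, 100)),
                max_features=["sqrt"],
                criterion=["gini", "entropy"],
            )
        return expand(
            max_depth=[100, 500, 1000, 1500, None],
            n_estimators=[100, 500, 1500],
            max_features=["sqrt", "log2", None],
            criterion=["gini", "entropy", "log_loss"],
        )

    if dataset_kind == "imbalanced":
        C = [round(0.7 + 0.1 * i, 1) for i in range(6)]  # 0.7 .. 1.2
        gamma = [round(0.1 + 0.1 * i, 1) for i in range(4)]  # 0.1 .. 0.4
        if family == "svm_rbf":
            return expand(C=C, gamma=gamma)
        return expand(C=C, gamma=gamma, degree=list(range(1, 6)))

    C = [10.0 ** e for e in range(-4, 5)]  # 1e-4 .. 1e4
    gamma = [10.0 ** e for e in range(-4, 3)]  # 1e-4 .. 1e2
    if family == "svm_rbf":
        return expand(C=C, gamma=gamma)
    return expand(C=C, gamma=gamma, degree=list(range(1, 7)))


def build_estimator(spec: ModelSpec, weights: Optional[ClassWeights] = None):
    p = spec.params
    cw = weights.as_dict() if weights is not None else None
    if spec.family == "random_forest":
        return RandomForestClassifier(
            n_estimators=int(p.get("n_estimators", 100)),
            max_depth=p.get("max_depth", None),
            max_features=p.get("max_features", "sqrt"),
            criterion=p.get("criterion", "gini"),
            class_weight=cw,
            random_state=spec.seed,
            n_jobs=1,
        )
    kernel = "rbf" if spec.family == "svm_rbf" else "poly"
    return SVC(
        kernel=kernel,
        C=float(p.get("C", 1.0)),
        gamma=p.get("gamma", "scale"),
        degree=int(p.get("degree", 3)),
        class_weight=cw,
        probability=True,
        random_state=spec.seed,
    )


def _fold_report(est, X_va, y_va) -> MetricsReport:
    pred = est.predict(X_va)
    rep = metrics(confusion(y_va, pred))
    try:
        rep.roc_auc = roc_auc(y_va, est.predict_proba(X_va)[:, 1])
    except UndefinedMetricError as exc:
        rep.undefined["roc_auc"] = exc.reason
    return rep


def grid_search_cv(
    X: np.ndarray,
    y: Sequence[int],
    family: str,
    grid: Sequence[Dict[str, object]],
    k: int = 10,
    seed: int = 0,
    selection_metric: str = "accuracy",
    use_class_weights: bool = True,
) -> GridSearchResult:
    """Exhaustive grid evaluation under stratified k-fold CV.

    Every configuration is scored by the mean of ``selection_metric`` over
    folds; degenerate folds (a validation fold missing a class) are skipped
    with a warning.  Ties go to the earlier grid entry.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(y) < k:
        raise InputError(f"need at least k={k} samples")
    if not grid:
        raise ConfigurationError("empty grid")
    weights = class_weights(y) if use_class_weights else None
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))

    best_score = -math.inf
    best_spec: Optional[ModelSpec] = None
    best_reports: List[MetricsReport] = []
    table: List[Dict[str, object]] = []

    for params in grid:
        spec = ModelSpec.make(family, seed=seed, **params)
        reports: List[MetricsReport] = []
        for tr, va in folds:
            if len(np.unique(y[va])) < 2 or len(np.unique(y[tr])) < 2:
                logger.warning("degenerate fold skipped for %s", params)
                continue
            est = build_estimator(spec, weights)
            est.fit(X[tr], y[tr])
            reports.append(_fold_report(est, X[va], y[va]))
        if not reports:
            continue
        per_metric = {}
        for m in ("sensitivity", "specificity", "accuracy", "balanced_accuracy",
                  "precision", "f1", "mcc", "kappa", "roc_auc"):
            vals = [getattr(r, m) for r in reports]
            vals = [v for v in vals if not math.isnan(v)]
            per_metric[f"{m}_mean"] = float(np.mean(vals)) if vals else math.nan
            per_metric[f"{m}_sd"] = float(np.std(vals)) if vals else math.nan
        row = {"params": dict(params), **per_metric}
        table.append(row)
        score = per_metric.get(f"{selection_metric}_mean", math.nan)
        if not math.isnan(score) and score > best_score:
            best_score = score
            best_spec = spec
            best_reports = reports

    if best_spec is None:
        raise ConfigurationError("no configuration could be evaluated")
    return GridSearchResult(best_spec=best_spec,
                            best_fold_reports=best_reports, cv_table=table)


def train(
    X: np.ndarray,
    y: Sequence[int],
    spec: ModelSpec,
    use_class_weights: bool = True,
    schema_json: Optional[str] = None,
    ad_reference: str = "all",
) -> ModelArtifact:
    """Fit the learner and freeze applicability-domain statistics.

    ``ad_reference`` selects whether AD distances are measured against all
    training compounds or only the active ones.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if ad_reference not in ("all", "active"):
        raise ConfigurationError("ad_reference must be 'all' or 'active'")
    weights = class_weights(y) if use_class_weights else None
    est = build_estimator(spec, weights)
    est.fit(X, y)
    ref = X if ad_reference == "all" else X[y == 1]
    mean = ref.mean(axis=0)
    cov = np.cov(ref, rowvar=False)
    cov_pinv = np.linalg.pinv(np.atleast_2d(cov))
    return ModelArtifact(
        spec=spec, model=est, train_mean=mean, cov_pinv=cov_pinv,
        n_features=X.shape[1], schema_json=schema_json,
        ad_reference=ad_reference,
    )


def ad_distances(artifact: ModelArtifact, X_new: np.ndarray) -> np.ndarray:
    diff = np.asarray(X_new, dtype=float) - artifact.train_mean
    q = np.einsum("ij,jk,ik->i", diff, artifact.cov_pinv, diff)
    return np.sqrt(np.maximum(q, 0.0))


def predict(
    artifact: ModelArtifact,
    X_new: np.ndarray,
    compound_ids: Optional[Sequence[str]] = None,
) -> List[PredictionResult]:
    """Label + active-class probability + AD distance for each query row."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 2 or X_new.shape[1] != artifact.n_features:
        raise InputError(
            f"fingerprint length mismatch: expected {artifact.n_features}, "
            f"got {X_new.shape[1] if X_new.ndim == 2 else 'non-matrix'}"
        )
    ids = [str(i) for i in (compound_ids if compound_ids is not None
                            else range(X_new.shape[0]))]
    proba = artifact.model.predict_proba(X_new)
    active_col = list(artifact.model.classes_).index(1)
    p_active = proba[:, active_col]
    labels = (p_active >= 0.5).astype(int)
    dists = ad_distances(artifact, X_new)
    return [
        PredictionResult(compound_id=i, predicted_label=int(l),
                         probability_active=float(p), ad_distance=float(d))
        for i, l, p, d in zip(ids, labels, p_active, dists)
    ]


def save_model(artifact: ModelArtifact, path) -> None:
    """Persist the artifact (binary) plus a JSON sidecar with the spec."""
    path = Path(path)
    joblib.dump(artifact, path)
    sidecar = {
        "family": artifact.spec.family,
        "hyperparameters": artifact.spec.params,
        "seed": artifact.spec.seed,
        "n_features": artifact.n_features,
        "ad_reference": artifact.ad_reference,
        "has_schema": artifact.schema_json is not None,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, default=str))


def load_model(path) -> ModelArtifact:
    return joblib.load(path)
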