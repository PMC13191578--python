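"""Preprocessing, the six-model zoo, stratified CV and confusion-matrix metrics.

Preprocessing winsorizes each feature at training-set quantiles (default
1%/99%) and then Z-scores it; both steps are fitted on the training data only.
The model zoo covers logistic regression, a decision tree, a 100-tree random
forest, gradient-boosted trees (XGBoost, softprob objective), 5-NN and PLS-DA
(a PLS regression on one-hot labels, class = argmax of the three responses).
Models are compared by stratified 5-fold CV with macro-F1 as the core metric,
which is robust to the 411/151/57 class imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.class_weight import compute_sample_weight
from xgboost import XGBClassifier

from .data_io import N_CLASSES, FeatureTable, stratified_kfold


# ---------------------------------------------------------------------------
# preprocessing


@dataclass
class PreprocessParams:
    """Per-feature capping bounds and Z-score moments, fitted on training data."""

    feature_names: list[str]
    cap_low: np.ndarray
    cap_high: np.ndarray
    mean: np.ndarray
    sd: np.ndarray


def fit_preprocess(
    train: FeatureTable, cap_quantiles: tuple[float, float] = (0.01, 0.99)
) -> PreprocessParams:
    if train.n_samples == 0:
        raise ValueError("cannot fit preprocessing on an empty table")
    lo_q, hi_q = cap_quantiles
    X = train.values
    cap_low = np.quantile(X, lo_q, axis=0)
    cap_high = np.quantile(X, hi_q, axis=0)
    capped = np.clip(X, cap_low, cap_high)
    mean = capped.mean(axis=0)
    sd = capped.std(axis=0, ddof=0)
    if np.any(sd == 0):
        j = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(
            f"feature {train.feature_names[j]!r} has zero variance after capping"
        )
    return PreprocessParams(list(train.feature_names), cap_low, cap_high, mean, sd)


def apply_preprocess(params: PreprocessParams, table: FeatureTable) -> FeatureTable:
    """Clip to the fitted caps, then Z-score; never refits on the argument."""
    if table.feature_names != params.feature_names:
        raise ValueError("feature names do not match preprocessing params")
    X = np.clip(table.values, params.cap_low, params.cap_high)
    X = (X - params.mean) / params.sd
    out = FeatureTable(
        list(table.sample_ids),
        list(table.feature_names),
        X,
        None if table.labels is None else table.labels.copy(),
    )
    return out


# ---------------------------------------------------------------------------
# model zoo


class PLSDAClassifier:
    """PLS-DA: PLS regression on one-hot labels, predict by response argmax."""

    def __init__(self, n_components: int = 3, max_iter: int = 500):
        self.n_components = n_components
        self.max_iter = max_iter

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        self.classes_ = np.arange(N_CLASSES)
        Y = np.eye(N_CLASSES)[y]
        k = min(self.n_components, X.shape[1], max(X.shape[0] - 1, 1))
        self._pls = PLSRegression(n_components=k, scale=False, max_iter=self.max_iter)
        self._pls.fit(X, Y)
        return self

    def predict(self, X):
        return np.argmax(self._pls.predict(np.asarray(X)), axis=1)


class BalancedXGB:
    """XGBoost with balanced per-sample weights standing in for class_weight."""

    def __init__(self, **kwargs):
        self._kwargs = kwargs

    def fit(self, X, y):
        self._model = XGBClassifier(**self._kwargs)
        w = compute_sample_weight("balanced", y)
        self._model.fit(np.asarray(X), np.asarray(y), sample_weight=w)
        return self

    def predict(self, X):
        return self._model.predict(np.asarray(X))

    def predict_proba(self, X):
        return self._model.predict_proba(np.asarray(X))


@dataclass
class ModelSpec:
    """A named, re-buildable classifier specification."""

    name: str
    build: Callable[[], object]


def model_zoo(seed: int = 42) -> list[ModelSpec]:
    """The six classifiers compared, with their fixed parameters."""
    return [
        ModelSpec(
            "LR",
            lambda: LogisticRegression(
                C=1.0, class_weight="balanced", random_state=seed, max_iter=1000
            ),
        ),
        ModelSpec(
            "DT",
            lambda: DecisionTreeClassifier(
                ccp_alpha=0.0, class_weight="balanced", random_state=seed
            ),
        ),
        ModelSpec(
            "RF",
            lambda: RandomForestClassifier(
                n_estimators=100,
                min_samples_leaf=1,
                min_samples_split=2,
                random_state=seed,
                n_jobs=1,
            ),
        ),
        ModelSpec(
            "XGBoost",
            lambda: BalancedXGB(
                n_estimators=100,
                objective="multi:softprob",
                num_class=N_CLASSES,
                random_state=seed,
                n_jobs=1,
                verbosity=0,
            ),
        ),
        ModelSpec(
            "KNN",
            lambda: KNeighborsClassifier(n_neighbors=5, algorithm="auto", leaf_size=30),
        ),
        ModelSpec("PLS-DA", lambda: PLSDAClassifier(n_components=3, max_iter=500)),
    ]


# ---------------------------------------------------------------------------
# metrics


@dataclass
class ModelMetrics:
    """Confusion matrix with per-class and macro precision/recall/F1 and accuracy.

    Macro values are unweighted means over the three classes; accuracy is
    trace/total.
    """

    confusion: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    accuracy: float

    def to_dict(self) -> dict:
        return {
            "confusion": np.asarray(self.confusion).tolist(),
            "per_class": {
                "precision": self.precision.tolist(),
                "recall": self.recall.tolist(),
                "f1": self.f1.tolist(),
            },
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "accuracy": self.accuracy,
        }


def confusion_matrix(y_true, y_pred) -> np.ndarray:
    """3x3 confusion matrix, rows = true class, columns = predicted."""
    return _sk_confusion(y_true, y_pred, labels=list(range(N_CLASSES)))


def metrics_from_confusion(cm) -> ModelMetrics:
    cm = np.asarray(cm, dtype=float)
    if cm.shape != (N_CLASSES, N_CLASSES) or np.any(cm < 0):
        raise ValueError("confusion matrix must be non-negative 3x3")
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(cm)
    col = cm.sum(axis=0)
    row = cm.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, tp / col, 0.0)
        recall = np.where(row > 0, tp / row, 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / np.where(pr > 0, pr, 1.0), 0.0)
    return ModelMetrics(
        confusion=cm,
        precision=precision,
        recall=recall,
        f1=f1,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        accuracy=float(tp.sum() / total),
    )


def evaluate(model, test: FeatureTable) -> ModelMetrics:
    """Confusion-matrix metrics of a fitted model on a labelled table."""
    if test.labels is None:
        raise ValueError("evaluation requires labels")
    pred = model.predict(test.values)
    return metrics_from_confusion(confusion_matrix(test.labels, pred))


def _mean_metrics(fold_metrics: Sequence[ModelMetrics]) -> ModelMetrics:
    """Arithmetic fold average; the confusion matrices are summed."""
    return ModelMetrics(
        confusion=np.sum([m.confusion for m in fold_metrics], axis=0),
        precision=np.mean([m.precision for m in fold_metrics], axis=0),
        recall=np.mean([m.recall for m in fold_metrics], axis=0),
        f1=np.mean([m.f1 for m in fold_metrics], axis=0),
        macro_precision=float(np.mean([m.macro_precision for m in fold_metrics])),
        macro_recall=float(np.mean([m.macro_recall for m in fold_metrics])),
        macro_f1=float(np.mean([m.macro_f1 for m in fold_metrics])),
        accuracy=float(np.mean([m.accuracy for m in fold_metrics])),
    )


def cross_validate(
    spec: ModelSpec,
    table: FeatureTable,
    n_folds: int = 5,
    seed: int = 42,
    preprocess: bool = True,
    cap_quantiles: tuple[float, float] = (0.01, 0.99),
) -> ModelMetrics:
    """Mean metrics over seeded stratified CV folds.

    Preprocessing (capping + Z-score) is refitted inside each fold on the
    training part only, so no statistics leak from the validation part.
    """
    if table.labels is None:
        raise ValueError("cross_validate requires labels")
    folds = stratified_kfold(table.labels, n_folds, seed)
    per_fold = []
    for train_idx, test_idx in folds:
        tr, te = table.take(train_idx), table.take(test_idx)
        if preprocess:
            params = fit_preprocess(tr, cap_quantiles)
            tr, te = apply_preprocess(params, tr), apply_preprocess(params, te)
        model = spec.build()
        model.fit(tr.values, tr.labels)
        per_fold.append(evaluate(model, te))
    return _mean_metrics(per_fold)


def compare_models(
    table: FeatureTable,
    specs: Sequence[ModelSpec] | None = None,
    n_folds: int = 5,
    seed: int = 42,
) -> list[tuple[str, ModelMetrics]]:
    """CV metrics for every model, ranked by mean macro-F1 (descending)."""
    specs = list(specs) if specs is not None else model_zoo(seed)
    results = [(s.name, cross_validate(s, table, n_folds, seed)) for s in specs]
    results.sort(key=lambda t: -t[1].macro_f1)
    return results
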