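"""Cross-validated classification and confusion-matrix metrics.

Three classifier families are compared, one per major category:

* ``ebt``  -- ensemble bagged trees: 30 bootstrap-resampled decision trees
  combined by probability averaging (vote fraction for pure leaves).
* ``svm``  -- support vector machine with a "fine" Gaussian kernel
  K(a, b) = exp(-||a - b||^2 / (2 rho^2)), rho = 1.4, box constraint 1,
  inputs standardised.
* ``ann``  -- a wide fully connected net: one hidden layer of 100 ReLU
  units, sigmoid output, iteration limit 1000, no regularisation,
  inputs standardised.

Each (mode, family) cell is scored under stratified 10-fold cross-validation
with the full confusion-matrix battery: accuracy, sensitivity, specificity,
precision, F1, NPV (all %) plus trapezoidal ROC AUC.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierSpec",
    "ConfusionMatrix",
    "EvalReport",
    "default_specs",
    "gaussian_kernel",
    "make_estimator",
    "kfold_split",
    "train_classifier",
    "model_scores",
    "confusion_metrics",
    "roc_auc",
    "cross_validate",
    "evaluate_pipeline",
]

FAMILIES = ("ebt", "svm", "ann")

METRIC_NAMES = (
    "accuracy",
    "sensitivity",
    "specificity",
    "precision",
    "f1",
    "npv",
)


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier family with its fixed hyperparameters."""

    family: str
    seed: int = 0
    # ebt
    n_learners: int = 30
    max_splits: int | None = None  # None -> n_train - 1 (unrestricted)
    # svm
    kernel_scale: float = 1.4  # rho in exp(-||a-b||^2 / (2 rho^2))
    box_constraint: float = 1.0
    # ann
    hidden_units: int = 100
    iteration_limit: int = 1000
    regularization: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.kernel_scale <= 0:
            raise ValueError("kernel_scale must be > 0")


def default_specs(seed: int = 0) -> list[ClassifierSpec]:
    return [ClassifierSpec(family=f, seed=seed) for f in FAMILIES]


def gaussian_kernel(a, b, scale: float = 1.4) -> float:
    """K(a, b) = exp(-||a - b||^2 / (2 scale^2))."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.exp(-np.sum((a - b) ** 2) / (2.0 * scale**2)))


def make_estimator(spec: ClassifierSpec, n_train: int):
    """Build the sklearn estimator for a spec, given the training-set size."""
    if spec.family == "ebt":
        max_splits = spec.max_splits if spec.max_splits is not None else n_train - 1
        tree = DecisionTreeClassifier(
            max_leaf_nodes=max_splits + 1, random_state=spec.seed
        )
        return BaggingClassifier(
            estimator=tree,
            n_estimators=spec.n_learners,
            random_state=spec.seed,
        )
    if spec.family == "svm":
        gamma = 1.0 / (2.0 * spec.kernel_scale**2)
        return make_pipeline(
            StandardScaler(),
            SVC(C=spec.box_constraint, kernel="rbf", gamma=gamma,
                random_state=spec.seed),
        )
    return make_pipeline(
        StandardScaler(),
        MLPClassifier(
            hidden_layer_sizes=(spec.hidden_units,),
            activation="relu",
            alpha=spec.regularization,
            max_iter=spec.iteration_limit,
            random_state=spec.seed,
        ),
    )


def train_classifier(X, y, spec: ClassifierSpec):
    """Fit a spec on (X, y); the model exposes predict and a continuous score."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("training data contains a single class")
    model = make_estimator(spec, n_train=X.shape[0])
    model.fit(X, y)
    return model


def model_scores(model, X) -> np.ndarray:
    """Continuous target-confidence score (monotone in P(target))."""
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=float)
    return np.asarray(model.predict_proba(X)[:, 1], dtype=float)


# ---------------------------------------------------------------------------
# folds and metrics
# ---------------------------------------------------------------------------

def kfold_split(labels, k: int = 10, seed: int = 0):
    """Stratified k-fold (train_idx, test_idx) pairs over ``len(labels)`` rows."""
    labels = np.asarray(labels)
    if labels.shape[0] < k:
        raise ValueError(f"{labels.shape[0]} rows cannot fill {k} folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(labels.shape[0]), labels))


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        )


def _ratio_pct(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.info("metric %s undefined (zero denominator)", name)
        return math.nan
    return 100.0 * num / den


def confusion_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, precision, F1 and NPV in percent.

    A metric whose denominator is zero is reported as NaN (undefined), never
    silently coerced to 0.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return {
        "accuracy": _ratio_pct(cm.tp + cm.tn, cm.total, "accuracy"),
        "sensitivity": _ratio_pct(cm.tp, cm.tp + cm.fn, "sensitivity"),
        "specificity": _ratio_pct(cm.tn, cm.tn + cm.fp, "specificity"),
        "precision": _ratio_pct(cm.tp, cm.tp + cm.fp, "precision"),
        "f1": _ratio_pct(cm.tp, cm.tp + 0.5 * (cm.fp + cm.fn), "f1"),
        "npv": _ratio_pct(cm.tn, cm.tn + cm.fn, "npv"),
    }


def roc_auc(scores, labels) -> tuple[float, np.ndarray]:
    """Trapezoidal AUC (%) plus the threshold-ordered (fpr, tpr) point list."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if np.unique(labels).size < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr)) * 100.0
    return auc, np.column_stack([fpr, tpr])


# ---------------------------------------------------------------------------
# cross-validated evaluation
# ---------------------------------------------------------------------------

def cross_validate(
    X, y, spec: ClassifierSpec, k: int = 10, seed: int = 0,
    roc_store: dict | None = None,
) -> pd.DataFrame:
    """Per-fold confusion metrics + AUC for one classifier on one table.

    When ``roc_store`` is a dict, the per-fold threshold-ordered (fpr, tpr)
    point lists are stored under the fold index.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    rows = []
    for fold, (tr, te) in enumerate(kfold_split(y, k=k, seed=seed)):
        model = train_classifier(X[tr], y[tr], spec)
        pred = model.predict(X[te])
        cm = ConfusionMatrix.from_predictions(y[te], pred)
        rec = {"fold": fold, "tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn}
        rec.update(confusion_metrics(cm))
        rec["auc"], points = roc_auc(model_scores(model, X[te]), y[te])
        if roc_store is not None:
            roc_store[fold] = points
        rows.append(rec)
    return pd.DataFrame(rows)


@dataclass
class EvalReport:
    """Per-fold and per-cell metrics for every (mode, classifier) pair."""

    folds: pd.DataFrame  # mode, family, fold, counts, metrics, auc
    summary: pd.DataFrame  # mode, family, mean of each metric
    best_mode: int
    best_family: str
    roc: dict | None = None  # (mode, family, fold) -> (fpr, tpr) point list

    def cell(self, mode: int, family: str) -> pd.Series:
        sel = (self.summary["mode"] == mode) & (self.summary["family"] == family)
        return self.summary[sel].iloc[0]


def evaluate_pipeline(
    mode_tables: dict[int, FeatureTable],
    specs: list[ClassifierSpec] | None = None,
    k: int = 10,
    seed: int = 0,
    keep_roc: bool = False,
) -> EvalReport:
    """Evaluate every classifier family on every mode's feature table.

    ``mode_tables`` maps mode id (1..M) to its (typically SMOTE-balanced)
    feature table; all tables must carry identical labels so the comparison
    is mode-wise, not data-wise.  The best cell is selected by mean
    accuracy; ties break by higher mean AUC, then lower mode index.
    """
    if specs is None:
        specs = default_specs(seed=seed)
    modes = sorted(mode_tables)
    ref = mode_tables[modes[0]].labels
    for m in modes[1:]:
        if not np.array_equal(mode_tables[m].labels, ref):
            raise ValueError(f"mode {m} labels differ from mode {modes[0]}")

    all_folds = []
    roc: dict | None = {} if keep_roc else None
    for m in modes:
        table = mode_tables[m]
        for spec in specs:
            store: dict | None = {} if keep_roc else None
            df = cross_validate(
                table.values, table.labels, spec, k=k, seed=seed, roc_store=store
            )
            if keep_roc:
                for fold, pts in store.items():
                    roc[(m, spec.family, fold)] = pts
            df.insert(0, "family", spec.family)
            df.insert(0, "mode", m)
            all_folds.append(df)
            logger.info(
                "mode %d / %s: accuracy %.2f%%, AUC %.2f%%",
                m, spec.family, df["accuracy"].mean(), df["auc"].mean(),
            )
    folds = pd.concat(all_folds, ignore_index=True)
    metric_cols = list(METRIC_NAMES) + ["auc"]
    summary = (
        folds.groupby(["mode", "family"], as_index=False)[metric_cols].mean()
    )
    best = summary.sort_values(
        by=["accuracy", "auc", "mode"], ascending=[False, False, True],
        kind="stable",
    ).iloc[0]
    return EvalReport(
        folds=folds,
        summary=summary,
        best_mode=int(best["mode"]),
        best_family=str(best["family"]),
        roc=roc,
    )
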