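"""Cross-validated evaluation: per-class metrics, ROC/AUC, parameter sweeps.

The protocol is stratified k-fold cross-validation (default k=10); every
sample is scored exactly once while held out, predictions are pooled into
one confusion matrix, and total accuracy is reported with the standard
deviation of the per-fold accuracies.  Per-class one-vs-rest ROC curves
are computed on the raw walk-arrival scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from . import classifier
from .graph_walk import GAMMA_GRID
from .io_formats import FeatureTable

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    """m x m counts; rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_order: list[str]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ClassMetrics:
    """Per-class sensitivity/precision/specificity plus total accuracy.

    ``per_class`` is a DataFrame indexed by class with columns
    sensitivity, precision, specificity, support; undefined rates (a class
    never predicted has no precision) are NaN and rendered "-" in reports.
    """

    per_class: pd.DataFrame
    total_accuracy: float
    accuracy_sd: float | None = None
    fold_accuracies: list[float] = field(default_factory=list)

    def to_tsv(self) -> str:
        df = self.per_class.copy()
        for col in ("sensitivity", "precision", "specificity"):
            df[col] = [
                "-" if np.isnan(v) else f"{v:.4f}" for v in df[col]
            ]
        lines = ["class\tsensitivity\tprecision\tspecificity\tsupport"]
        for cls, row in df.iterrows():
            lines.append(
                f"{cls}\t{row['sensitivity']}\t{row['precision']}\t"
                f"{row['specificity']}\t{int(row['support'])}"
            )
        sd = "" if self.accuracy_sd is None else f"±{self.accuracy_sd:.4f}"
        lines.append(f"total_accuracy\t{self.total_accuracy:.4f}{sd}")
        return "\n".join(lines) + "\n"


@dataclass
class ROCResult:
    """Per-class one-vs-rest ROC curves and AUCs (NaN for absent classes)."""

    curves: dict[str, tuple[np.ndarray, np.ndarray]]  # class -> (fpr, tpr)
    auc: dict[str, float]


def stratified_kfold(
    labels: Sequence[str], k: int, seed: int = 0
) -> list[np.ndarray]:
    """Partition indices into k class-stratified folds (shuffled, seeded).

    Each class's members are shuffled and dealt round-robin across the
    folds with a running pointer, so fold sizes and per-fold class
    proportions match the global ones within rounding.  A class with fewer
    members than k appears in only some folds (warned), which keeps
    leave-one-out (k = n) well defined.
    """
    labels = np.asarray(list(labels), dtype=object)
    n = len(labels)
    if k < 2:
        raise ValueError(f"k must be at least 2, got {k}")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples ({n})")
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        logger.warning(
            "a class has only %d member(s) (< k=%d); it will be absent "
            "from some folds", int(counts.min()), k,
        )
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    pointer = 0
    for c in classes:
        members = rng.permutation(np.flatnonzero(labels == c))
        for idx in members:
            folds[pointer % k].append(int(idx))
            pointer += 1
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def confusion(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    class_order: Sequence[str],
) -> ConfusionMatrix:
    """Count confusion: counts[a, b] = #{true class a, predicted class b}."""
    true_labels, predicted_labels = list(true_labels), list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("true and predicted label lists differ in length")
    if not true_labels:
        raise ValueError("empty label lists")
    index = {c: j for j, c in enumerate(class_order)}
    outside = [x for x in set(true_labels) | set(predicted_labels) if x not in index]
    if outside:
        raise ValueError(f"label(s) outside class order: {sorted(outside)}")
    counts = np.zeros((len(class_order), len(class_order)), dtype=int)
    for a, b in zip(true_labels, predicted_labels):
        counts[index[a], index[b]] += 1
    return ConfusionMatrix(counts=counts, class_order=list(class_order))


def class_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """Per-class sensitivity, precision and specificity from a confusion matrix.

    sensitivity_j = TP/(TP+FN); precision_j = TP/(TP+FP) (NaN when class j
    is never predicted); specificity_j = TN/(TN+FP); total accuracy is the
    trace over the grand total.
    """
    C = cm.counts
    if C.sum() == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(C).astype(float)
    fn = C.sum(axis=1) - tp
    fp = C.sum(axis=0) - tp
    tn = C.sum() - tp - fn - fp
    with np.errstate(divide="ignore", invalid="ignore"):
        sensitivity = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        precision = np.where(tp + fp > 0, tp / (tp + fp), np.nan)
        specificity = np.where(tn + fp > 0, tn / (tn + fp), np.nan)
    per_class = pd.DataFrame(
        {
            "sensitivity": sensitivity,
            "precision": precision,
            "specificity": specificity,
            "support": C.sum(axis=1),
        },
        index=pd.Index(cm.class_order, name="class"),
    )
    return ClassMetrics(
        per_class=per_class,
        total_accuracy=float(np.trace(C) / C.sum()),
    )


def roc_one_vs_rest(
    scores: classifier.ScoreMatrix,
    true_labels: Sequence[str],
    class_order: Sequence[str] | None = None,
) -> ROCResult:
    """One-vs-rest ROC per class on the raw walk-arrival score rows.

    Classes absent from the true labels get an empty curve and NaN AUC.
    """
    order = list(class_order) if class_order is not None else scores.class_order
    matrix = scores.scores
    true_labels = list(true_labels)
    if matrix.shape[1] != len(true_labels):
        raise ValueError("score columns do not align with true labels")
    curves: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    aucs: dict[str, float] = {}
    for j, c in enumerate(order):
        y_true = np.array([1 if lab == c else 0 for lab in true_labels])
        if y_true.sum() == 0 or y_true.sum() == len(y_true):
            curves[c] = (np.array([]), np.array([]))
            aucs[c] = float("nan")
            continue
        fpr, tpr, _ = _sk_roc_curve(y_true, matrix[j])
        curves[c] = (fpr, tpr)
        aucs[c] = float(_sk_auc(fpr, tpr))
    return ROCResult(curves=curves, auc=aucs)


@dataclass
class CVResult:
    """Everything a cross-validation run produces."""

    metrics: ClassMetrics
    roc: ROCResult
    confusion: ConfusionMatrix
    predictions: list[str]
    scores: classifier.ScoreMatrix
    fold_log: pd.DataFrame


def cross_validate(
    table: FeatureTable,
    k: int = 10,
    gamma: float = 1.0,
    alpha: float = 0.75,
    t: int = 5,
    lambda_reg: float = 1e-4,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold cross-validation of the RaWa classifier.

    Each fold is held out once, the model fit on the rest scores it, and
    the pooled predictions yield the confusion matrix, per-class metrics,
    total accuracy (with across-fold SD) and per-class ROC curves.
    """
    if table.labels is None:
        raise ValueError("cross_validate requires a labeled table")
    class_order = table.class_set
    folds = stratified_kfold(table.labels, k, seed)
    n = table.n
    pooled_pred: list[str | None] = [None] * n
    pooled_scores = np.full((len(class_order), n), np.nan)
    fold_rows = []
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        model = classifier.fit(
            table.subset(train_idx), gamma=gamma, alpha=alpha, t=t,
            lambda_reg=lambda_reg, seed=seed,
        )
        sm = classifier.predict_scores(model, table.X[test_idx])
        pred = classifier.predict_labels(sm)
        # Folds may miss classes entirely absent from their training part;
        # map the fold's class rows into the global order.
        row_of = {c: j for j, c in enumerate(sm.class_order)}
        for col, i in enumerate(test_idx):
            pooled_pred[i] = pred[col]
            for j, c in enumerate(class_order):
                if c in row_of:
                    pooled_scores[j, i] = sm.scores[row_of[c], col]
                else:
                    pooled_scores[j, i] = -np.inf
        correct = sum(pred[col] == table.labels[i] for col, i in enumerate(test_idx))
        fold_rows.append(
            {"fold": f, "n_test": len(test_idx),
             "accuracy": correct / len(test_idx)}
        )
    pooled_scores[np.isneginf(pooled_scores)] = np.nanmin(pooled_scores) - 1.0
    assert all(p is not None for p in pooled_pred)
    cm = confusion(table.labels, pooled_pred, class_order)
    metrics = class_metrics(cm)
    fold_log = pd.DataFrame(fold_rows)
    metrics.fold_accuracies = fold_log["accuracy"].tolist()
    metrics.accuracy_sd = float(np.std(fold_log["accuracy"], ddof=1))
    score_matrix = classifier.ScoreMatrix(scores=pooled_scores, class_order=class_order)
    roc = roc_one_vs_rest(score_matrix, table.labels, class_order)
    return CVResult(
        metrics=metrics, roc=roc, confusion=cm,
        predictions=list(pooled_pred), scores=score_matrix, fold_log=fold_log,
    )


def parameter_sweep(
    table: FeatureTable,
    alphas: Sequence[float] = (0.05, 0.25, 0.5, 0.75, 0.95),
    t_max: int = 30,
    k: int = 10,
    gamma: float = 1.0,
    lambda_reg: float = 1e-4,
    seed: int = 0,
) -> pd.DataFrame:
    """CV accuracy over the (laziness, steps) grid, t = 1..t_max.

    Returns a DataFrame indexed by alpha with one column per step count —
    the table behind accuracy-vs-steps curves.
    """
    grid = np.zeros((len(alphas), t_max))
    for i, a in enumerate(alphas):
        for t in range(1, t_max + 1):
            result = cross_validate(
                table, k=k, gamma=gamma, alpha=a, t=t,
                lambda_reg=lambda_reg, seed=seed,
            )
            grid[i, t - 1] = result.metrics.total_accuracy
    return pd.DataFrame(
        grid,
        index=pd.Index(list(alphas), name="alpha"),
        columns=pd.Index(range(1, t_max + 1), name="t"),
    )


def gamma_grid_search(
    table: FeatureTable,
    k: int = 10,
    alpha: float = 0.75,
    t: int = 5,
    lambda_reg: float = 1e-4,
    seed: int = 0,
    grid: Sequence[float] = GAMMA_GRID,
) -> tuple[float, pd.DataFrame]:
    """Pick the kernel bandwidth by k-fold CV over the odd-power-of-two grid.

    Returns the best gamma (ties to the smaller value) and the per-gamma
    accuracy table.
    """
    rows = []
    for g in grid:
        result = cross_validate(
            table, k=k, gamma=g, alpha=alpha, t=t,
            lambda_reg=lambda_reg, seed=seed,
        )
        rows.append({"gamma": g, "accuracy": result.metrics.total_accuracy})
    df = pd.DataFrame(rows).sort_values("gamma", kind="stable").reset_index(drop=True)
    best = df.loc[df["accuracy"].idxmax(), "gamma"]  # idxmax -> first = smallest
    return float(best), df
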