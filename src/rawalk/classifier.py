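"""The RaWa random-walk classifier.

Training builds a complete RBF similarity graph over the labeled feature
vectors and weighs two complementary stratified halves of the training set
by how well each predicts the other.  The fitted model is the projection

    F_hat (K + lambda*I)^+   with   F_hat = Y_tilde Q^t,

where Y_tilde scales each one-hot label column by its half's weight
(alpha_S or alpha_T), Q = alpha*I + (1-alpha)*P is the lazy walk operator
on the training graph, and K the RBF kernel/weight matrix.  A test point x
receives per-class scores F(x) = F_hat (K + lambda*I)^+ k(X, x) — the
t-step walk-arrival mass on each class — and the argmax class.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .graph_walk import (
    lazy_operator,
    rbf_kernel,
    regularized_pinv,
    transition_from_weights,
    walk_power,
)
from .io_formats import FeatureTable

logger = logging.getLogger(__name__)


@dataclass
class StateMatrix:
    """m x n 0/1 matrix whose column i one-hot encodes the class of sample i."""

    Y: np.ndarray
    class_order: list[str]


@dataclass
class SplitWeights:
    """Complementary-split bookkeeping: losses and the derived weights."""

    S_indices: np.ndarray
    T_indices: np.ndarray
    eps_S: float
    eps_T: float
    alpha_S: float
    alpha_T: float
    total_loss: float


@dataclass
class ScoreMatrix:
    """m classes x q test points of walk-arrival scores f_ji."""

    scores: np.ndarray
    class_order: list[str]


@dataclass
class WalkModel:
    """A fitted RaWa model (training features, weighted states, projection)."""

    X_train: np.ndarray
    class_order: list[str]
    Y_tilde: np.ndarray
    gamma: float
    alpha: float
    t: int
    lambda_reg: float
    projection: np.ndarray  # m x n: Y_tilde Q^t (K + lambda I)^+
    split: SplitWeights | None = None

    def save(self, path: str | Path) -> None:
        """Serialize to a JSON container (projection stored for speed)."""
        payload = {
            "format": "rawalk-model",
            "version": 1,
            "class_order": self.class_order,
            "gamma": self.gamma,
            "alpha": self.alpha,
            "t": self.t,
            "lambda_reg": self.lambda_reg,
            "X_train": self.X_train.tolist(),
            "Y_tilde": self.Y_tilde.tolist(),
            "projection": self.projection.tolist(),
        }
        if self.split is not None:
            payload["split"] = {
                "S_indices": self.split.S_indices.tolist(),
                "T_indices": self.split.T_indices.tolist(),
                "eps_S": self.split.eps_S,
                "eps_T": self.split.eps_T,
                "alpha_S": self.split.alpha_S,
                "alpha_T": self.split.alpha_T,
                "total_loss": self.split.total_loss,
            }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "WalkModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "rawalk-model":
            raise ValueError(f"{path}: not a rawalk model file")
        split = None
        if "split" in payload:
            s = payload["split"]
            split = SplitWeights(
                S_indices=np.asarray(s["S_indices"], dtype=int),
                T_indices=np.asarray(s["T_indices"], dtype=int),
                eps_S=s["eps_S"], eps_T=s["eps_T"],
                alpha_S=s["alpha_S"], alpha_T=s["alpha_T"],
                total_loss=s["total_loss"],
            )
        return cls(
            X_train=np.asarray(payload["X_train"], dtype=float),
            class_order=list(payload["class_order"]),
            Y_tilde=np.asarray(payload["Y_tilde"], dtype=float),
            gamma=payload["gamma"], alpha=payload["alpha"], t=payload["t"],
            lambda_reg=payload["lambda_reg"],
            projection=np.asarray(payload["projection"], dtype=float),
            split=split,
        )


def one_hot_states(labels: Sequence[str], class_order: Sequence[str]) -> StateMatrix:
    """Encode labels as an m x n state matrix with one-hot columns."""
    index = {c: j for j, c in enumerate(class_order)}
    unknown = [lab for lab in labels if lab not in index]
    if unknown:
        raise ValueError(f"label(s) not in class order: {sorted(set(unknown))}")
    Y = np.zeros((len(class_order), len(labels)))
    for i, lab in enumerate(labels):
        Y[index[lab], i] = 1.0
    return StateMatrix(Y=Y, class_order=list(class_order))


def stratified_half_split(
    labels: Sequence[str], seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Split indices into two balanced halves S, T, stratified by class.

    Within each class the members are shuffled with the seeded generator
    and dealt alternately to the two sides, so |S| and |T| differ by at
    most the number of odd-sized classes.  Deterministic given the seed.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("empty label list")
    rng = np.random.default_rng(seed)
    S: list[int] = []
    T: list[int] = []
    for c in sorted(set(labels)):
        members = np.flatnonzero(np.array(labels, dtype=object) == c)
        members = rng.permutation(members)
        S.extend(members[0::2])
        T.extend(members[1::2])
    return np.sort(np.array(S, dtype=int)), np.sort(np.array(T, dtype=int))


def _subset_scores(
    X_from: np.ndarray,
    Y_from: np.ndarray,
    X_to: np.ndarray,
    gamma: float,
    alpha: float,
    t: int,
    lambda_reg: float,
) -> np.ndarray:
    """Walk-arrival scores of X_to under a model built on (X_from, Y_from)."""
    W = rbf_kernel(X_from, X_from, gamma)
    Q = lazy_operator(transition_from_weights(W), alpha)
    proj = Y_from @ walk_power(Q, t) @ regularized_pinv(W, lambda_reg)
    return proj @ rbf_kernel(X_from, X_to, gamma)


def cross_prediction_loss(
    X: np.ndarray,
    Y: np.ndarray,
    S_indices: np.ndarray,
    T_indices: np.ndarray,
    gamma: float = 1.0,
    alpha: float = 0.75,
    t: int = 5,
    lambda_reg: float = 1e-4,
) -> tuple[float, float]:
    """Squared-Frobenius losses of the two halves predicting each other.

    eps_S = || Y_S Q_S^t (W_S + lambda I)^+ w(S, T) - Y_T ||_F^2 and
    symmetrically eps_T; a small loss means the half generalizes well to
    its complement.
    """
    if len(S_indices) == 0 or len(T_indices) == 0:
        raise ValueError("both split halves must be non-empty")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    F_S = _subset_scores(X[S_indices], Y[:, S_indices], X[T_indices],
                         gamma, alpha, t, lambda_reg)
    F_T = _subset_scores(X[T_indices], Y[:, T_indices], X[S_indices],
                         gamma, alpha, t, lambda_reg)
    eps_S = float(np.linalg.norm(F_S - Y[:, T_indices], "fro") ** 2)
    eps_T = float(np.linalg.norm(F_T - Y[:, S_indices], "fro") ** 2)
    return eps_S, eps_T


def split_weights(eps_S: float, eps_T: float) -> tuple[float, float]:
    """Subset weights alpha_S = eps_T/(eps_S+eps_T), alpha_T = eps_S/(...).

    The half with the smaller cross-prediction loss gets the larger
    weight; the weights sum to 1.  Both losses zero is the degenerate
    perfect case and yields (0.5, 0.5).
    """
    if eps_S < 0 or eps_T < 0:
        raise ValueError("losses must be non-negative")
    total = eps_S + eps_T
    if total == 0:
        return 0.5, 0.5
    return eps_T / total, eps_S / total


def total_loss(eps_S: float, eps_T: float) -> float:
    """Combined split loss eps_S*eps_T/(eps_S+eps_T); 0 when both are 0."""
    if eps_S < 0 or eps_T < 0:
        raise ValueError("losses must be non-negative")
    total = eps_S + eps_T
    if total == 0:
        return 0.0
    return eps_S * eps_T / total


def fit(
    table: FeatureTable,
    gamma: float = 1.0,
    alpha: float = 0.75,
    t: int = 5,
    lambda_reg: float = 1e-4,
    seed: int = 0,
    n_splits: int = 1,
) -> WalkModel:
    """Fit a RaWa model on a labeled feature table.

    Performs the complementary half split, computes the two cross-
    prediction losses with the same (gamma, alpha, t, lambda) as the final
    model, derives the half weights, and precomputes the projection
    Y_tilde Q^t (K + lambda I)^+.  With ``n_splits`` > 1 the weights are
    averaged over that many independent seeded splits.
    """
    if table.labels is None:
        raise ValueError("fit requires a labeled feature table")
    if table.n < 2:
        raise ValueError("fit requires at least 2 samples")
    class_order = table.class_set
    if len(class_order) == 1:
        warnings.warn(
            "single-class training set: every prediction will be that class",
            stacklevel=2,
        )
    Y = one_hot_states(table.labels, class_order).Y

    weight = np.empty(table.n)
    alpha_S_acc = alpha_T_acc = eps_S_last = eps_T_last = 0.0
    split: SplitWeights | None = None
    for r in range(n_splits):
        S_idx, T_idx = stratified_half_split(table.labels, seed=seed + r)
        eps_S, eps_T = cross_prediction_loss(
            table.X, Y, S_idx, T_idx, gamma, alpha, t, lambda_reg
        )
        a_S, a_T = split_weights(eps_S, eps_T)
        alpha_S_acc += a_S
        alpha_T_acc += a_T
        eps_S_last, eps_T_last = eps_S, eps_T
        if r == 0:
            split = SplitWeights(
                S_indices=S_idx, T_indices=T_idx, eps_S=eps_S, eps_T=eps_T,
                alpha_S=a_S, alpha_T=a_T, total_loss=total_loss(eps_S, eps_T),
            )
    alpha_S = alpha_S_acc / n_splits
    alpha_T = alpha_T_acc / n_splits
    assert split is not None
    if n_splits > 1:
        split.alpha_S, split.alpha_T = alpha_S, alpha_T
    logger.info(
        "fit: eps_S=%.6g eps_T=%.6g total_loss=%.6g alpha_S=%.4f alpha_T=%.4f",
        eps_S_last, eps_T_last, total_loss(eps_S_last, eps_T_last),
        alpha_S, alpha_T,
    )

    # Column i of Y_tilde is scaled by its half's weight (membership order
    # preserved; no physical reordering into [Y_S, Y_T] blocks).
    weight[:] = alpha_T
    weight[split.S_indices] = alpha_S
    Y_tilde = Y * weight[None, :]

    K = rbf_kernel(table.X, table.X, gamma)
    Q = lazy_operator(transition_from_weights(K), alpha)
    projection = Y_tilde @ walk_power(Q, t) @ regularized_pinv(K, lambda_reg)
    return WalkModel(
        X_train=np.asarray(table.X, dtype=float),
        class_order=class_order,
        Y_tilde=Y_tilde,
        gamma=gamma, alpha=alpha, t=t, lambda_reg=lambda_reg,
        projection=projection,
        split=split,
    )


def predict_scores(model: WalkModel, X_test: np.ndarray) -> ScoreMatrix:
    """Per-class walk-arrival scores F(x) = projection . k(X_train, x)."""
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    if X_test.shape[1] != model.X_train.shape[1]:
        raise ValueError(
            f"test dimensionality {X_test.shape[1]} does not match "
            f"training dimensionality {model.X_train.shape[1]}"
        )
    k = rbf_kernel(model.X_train, X_test, model.gamma)
    return ScoreMatrix(scores=model.projection @ k, class_order=model.class_order)


def predict_labels(
    scores: ScoreMatrix | np.ndarray, class_order: Sequence[str] | None = None
) -> list[str]:
    """Argmax class per test column; ties break to the lowest class index."""
    if isinstance(scores, ScoreMatrix):
        matrix, order = scores.scores, scores.class_order
    else:
        matrix = np.asarray(scores, dtype=float)
        if class_order is None:
            raise ValueError("class_order required when passing a bare matrix")
        order = list(class_order)
    if matrix.size == 0:
        raise ValueError("empty score matrix")
    if np.any(np.isnan(matrix)):
        raise ValueError("score matrix contains NaN")
    return [order[j] for j in matrix.argmax(axis=0)]
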