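"""Similarity-graph construction and random-walk operators.

The classifier views the training set as a complete weighted graph whose
edge weights are RBF similarities w_ij = exp(-gamma * ||x_i - x_j||^2).
This module builds that weight matrix, the row-stochastic transition
operator P = D^-1 W, the lazy operator Q = alpha*I + (1-alpha)*P, its
t-step powers, and the regularized Moore-Penrose pseudo-inverse
(K + lambda*I)^+ used by the prediction rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.metrics.pairwise import rbf_kernel as _sk_rbf

#: Canonical gamma search space: the odd powers of two from 2^-11 to 2^11.
GAMMA_GRID: tuple[float, ...] = tuple(2.0**p for p in range(-11, 12, 2))


@dataclass(frozen=True)
class KernelParams:
    """RBF kernel bandwidth gamma = 1 / (2 sigma^2)."""

    gamma: float = 1.0

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")


def rbf_kernel(A: np.ndarray, B: np.ndarray, params: KernelParams | float = 1.0) -> np.ndarray:
    """Pairwise RBF similarities exp(-gamma * ||a_i - b_j||^2).

    Serves both as the graph weight matrix W (A = B = X) and as the
    test-point similarity column k(X, x).
    """
    gamma = params.gamma if isinstance(params, KernelParams) else float(params)
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"dimension mismatch: {A.shape[1]} vs {B.shape[1]}")
    return _sk_rbf(A, B, gamma=gamma)


def transition_from_weights(W: np.ndarray) -> np.ndarray:
    """Row-normalize a weight matrix: P = D^-1 W with D = diag(W 1_n)."""
    W = np.asarray(W, dtype=float)
    row_sums = W.sum(axis=1)
    if np.any(row_sums <= 0):
        bad = int(np.flatnonzero(row_sums <= 0)[0])
        raise ValueError(f"row {bad} of W has non-positive sum; cannot normalize")
    return W / row_sums[:, None]


def lazy_operator(P: np.ndarray, alpha: float) -> np.ndarray:
    """Lazy walk operator Q = alpha*I + (1 - alpha)*P.

    alpha is the probability of staying put at each step.  The open
    interval (0, 1) is the intended range; the endpoints are accepted as
    degenerate cases (alpha=0 gives P, alpha=1 the identity).
    """
    if not 0 <= alpha <= 1:
        raise ValueError(f"laziness alpha must lie in [0, 1], got {alpha}")
    P = np.asarray(P, dtype=float)
    return alpha * np.eye(P.shape[0]) + (1.0 - alpha) * P


def walk_power(Q: np.ndarray, t: int) -> np.ndarray:
    """t-step walk operator Q^t (t = 0 gives the identity)."""
    if t < 0:
        raise ValueError(f"step count t must be non-negative, got {t}")
    Q = np.asarray(Q, dtype=float)
    return np.linalg.matrix_power(Q, t)


def regularized_pinv(K: np.ndarray, lambda_reg: float = 1e-4) -> np.ndarray:
    """Moore-Penrose pseudo-inverse of (K + lambda*I) for symmetric K.

    Computed by symmetric eigendecomposition with the standard relative
    cutoff (eigenvalues below n * eps * max|eigenvalue| are zeroed); equals
    the exact inverse whenever K + lambda*I is well-conditioned.
    """
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError(f"K must be square, got {K.shape}")
    if np.any(np.isnan(K)):
        raise ValueError("K contains NaN entries")
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("K is not symmetric within tolerance")
    if lambda_reg < 0:
        raise ValueError("lambda_reg must be non-negative")
    return scipy.linalg.pinvh(K + lambda_reg * np.eye(K.shape[0]))
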