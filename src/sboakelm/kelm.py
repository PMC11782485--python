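"""Kernel Extreme Learning Machine (KELM).

A KELM is the kernel-trick form of the extreme learning machine: instead
of a random hidden layer H, the Gram matrix Omega_ij = K(x_i, x_j) plays
the role of H H^T, and the dual coefficients solve the ridge-regularized
system

    (I/C + Omega) beta = T

where C > 0 is the penalty parameter and T the encoded targets.  New
points are scored as K(x_new, X_train) @ beta.  The Gaussian RBF kernel
K(a, b) = exp(-||a - b||^2 / (2 c^2)) is used throughout, with kernel
width c > 0.

Binary labels are encoded as a single +/-1 column (positive class = the
larger label) and thresholded at 0, ties going to the positive class.  A
multi-class one-hot (+/-1) path with argmax decision is included for
completeness but the intended task is binary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import solve
from scipy.spatial.distance import cdist

__all__ = [
    "KELMModel",
    "rbf_kernel_matrix",
    "kelm_train",
    "kelm_decision",
    "kelm_predict",
    "save_model",
    "load_model",
]


def rbf_kernel_matrix(A: np.ndarray, B: np.ndarray, c: float) -> np.ndarray:
    """Gaussian RBF Gram matrix K_ij = exp(-||a_i - b_j||^2 / (2 c^2))."""
    if c <= 0:
        raise ValueError(f"kernel width c must be positive, got {c}")
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"feature dimensions differ: {A.shape[1]} vs {B.shape[1]}")
    sq = cdist(A, B, metric="sqeuclidean")
    return np.exp(-sq / (2.0 * c * c))


@dataclass
class KELMModel:
    """Trained KELM: stored training inputs plus dual coefficients."""

    train_X: np.ndarray
    dual_coef: np.ndarray  # n x m, m = 1 (binary) or n_classes (one-hot)
    penalty_C: float
    kernel_width_c: float
    classes: np.ndarray
    single_class: bool = field(default=False)

    @property
    def is_binary(self) -> bool:
        return self.dual_coef.shape[1] == 1


def _encode_targets(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    if classes.size <= 2:
        # +/-1 column; with a single observed class every target is +1
        pos = classes[-1]
        return np.where(y == pos, 1.0, -1.0)[:, None]
    onehot = (y[:, None] == classes[None, :]).astype(float)
    return 2.0 * onehot - 1.0


def kelm_train(X: np.ndarray, y: np.ndarray, C: float, c: float) -> KELMModel:
    """Solve (I/C + Omega) beta = T for the dual coefficients.

    Uses a symmetric positive-definite solve, never an explicit inverse.
    Training with a single observed class is allowed but flagged
    (``single_class``); such a model predicts that class everywhere.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y have different numbers of rows")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    if C <= 0:
        raise ValueError(f"penalty C must be positive, got {C}")
    classes = np.unique(y)
    T = _encode_targets(y, classes)
    omega = rbf_kernel_matrix(X, X, c)
    lhs = omega + np.eye(X.shape[0]) / C
    try:
        dual = solve(lhs, T, assume_a="pos")
    except np.linalg.LinAlgError as err:  # pragma: no cover - near-impossible for C < inf
        raise np.linalg.LinAlgError(
            "kernel system is singular (duplicate rows at extreme C?); "
            "add ridge jitter by lowering C"
        ) from err
    return KELMModel(
        train_X=X.copy(),
        dual_coef=dual,
        penalty_C=float(C),
        kernel_width_c=float(c),
        classes=classes,
        single_class=classes.size == 1,
    )


def kelm_decision(model: KELMModel, Xnew: np.ndarray) -> np.ndarray:
    """Decision scores K(Xnew, X_train) @ dual_coef.

    Binary models return a length-q vector; multi-class models a q x m
    matrix of per-class scores.
    """
    Xnew = np.atleast_2d(np.asarray(Xnew, dtype=float))
    if Xnew.shape[0] == 0:
        shape = (0,) if model.is_binary else (0, model.dual_coef.shape[1])
        return np.empty(shape)
    K = rbf_kernel_matrix(Xnew, model.train_X, model.kernel_width_c)
    scores = K @ model.dual_coef
    return scores[:, 0] if model.is_binary else scores


def kelm_predict(model: KELMModel, Xnew: np.ndarray) -> np.ndarray:
    """Labels from decision scores; binary ties (score = 0) go positive."""
    scores = kelm_decision(model, Xnew)
    if model.single_class:
        return np.full(np.atleast_1d(scores).shape[0], model.classes[0])
    if model.is_binary:
        return np.where(scores >= 0, model.classes[-1], model.classes[0])
    return model.classes[np.argmax(scores, axis=1)]


def save_model(model: KELMModel, path) -> None:
    """Serialize to a single JSON file (17 significant digits)."""
    payload = {
        "train_X": model.train_X.tolist(),
        "dual_coef": model.dual_coef.tolist(),
        "penalty_C": model.penalty_C,
        "kernel_width_c": model.kernel_width_c,
        "classes": model.classes.tolist(),
        "single_class": model.single_class,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> KELMModel:
    payload = json.loads(Path(path).read_text())
    return KELMModel(
        train_X=np.asarray(payload["train_X"], dtype=float),
        dual_coef=np.asarray(payload["dual_coef"], dtype=float),
        penalty_C=payload["penalty_C"],
        kernel_width_c=payload["kernel_width_c"],
        classes=np.asarray(payload["classes"]),
        single_class=payload["single_class"],
    )
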