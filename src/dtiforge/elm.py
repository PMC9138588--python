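"""Extreme learning machine (ELM) classifier.

A single-hidden-layer feedforward network whose input weights W and
hidden offsets b are drawn once at random and never trained.  With
hidden-layer output matrix

    S[j, i] = g(W_i . X_j + b_i),        S in R^{L x N}

the output weights V are the minimum-norm least-squares solution of
the linear system S V = P, where P holds the target encodings — the
Moore-Penrose solution, which is both the minimizer of ||S V - P|| and
the smallest-norm such minimizer.  Training therefore costs one
least-squares solve; there is no iterative optimization.

Binary targets are encoded one-hot ((1,0) negative / (0,1) positive)
and the continuous decision score of a sample is the difference
between its positive- and negative-column outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ShapeError

__all__ = [
    "ELMModel",
    "elm_hidden",
    "elm_train",
    "elm_predict",
    "elm_decide",
    "DEFAULT_N_HIDDEN",
]

DEFAULT_N_HIDDEN = 1000  # capped at 10 * n_samples in elm_train

_ACT = {
    "sigmoid": lambda z: np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.abs(z))),
                                  np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z)))),
    "tanh": np.tanh,
    "relu": lambda z: np.maximum(z, 0.0),
}


@dataclass
class ELMModel:
    """Frozen random hidden layer + least-squares output weights."""

    input_weights: np.ndarray       # (N, d)
    offsets: np.ndarray             # (N,)
    output_weights: np.ndarray      # (N, m)
    activation: str
    n_hidden: int
    seed: int


def _activate(name: str, z: np.ndarray) -> np.ndarray:
    try:
        return _ACT[name](z)
    except KeyError:
        raise ShapeError(f"unknown ELM activation {name!r}") from None


def elm_hidden(m: ELMModel, X: np.ndarray) -> np.ndarray:
    """Hidden-layer output S with S[j, i] = g(W_i . X_j + b_i)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.size and X.shape[1] != m.input_weights.shape[1]:
        raise ShapeError(
            f"feature length {X.shape[1]} != model input dim "
            f"{m.input_weights.shape[1]}"
        )
    return _activate(m.activation, X @ m.input_weights.T + m.offsets)


def elm_train(
    X: np.ndarray,
    P: np.ndarray,
    n_hidden: int | None = None,
    seed: int = 0,
    activation: str = "sigmoid",
) -> ELMModel:
    """Fit output weights by minimum-norm least squares.

    W and b are drawn from a seeded uniform(-1, 1); V solves
    min ||S V - P|| with the smallest norm (rank-revealing SVD solve,
    relative singular-value cutoff 1e-12).  Deterministic given seed.
    ``n_hidden`` defaults to min(1000, 10 * L).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    P = np.asarray(P, dtype=float)
    if P.ndim == 1:
        P = P[:, None]
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    if not np.isfinite(P).all():
        raise ValueError("non-finite target values")
    L, d = X.shape
    if L < 1:
        raise ShapeError("need at least one training sample")
    if P.shape[0] != L:
        raise ShapeError(f"{L} samples but {P.shape[0]} target rows")
    if n_hidden is None:
        n_hidden = min(DEFAULT_N_HIDDEN, 10 * L)

    rng = np.random.default_rng(seed)
    W = rng.uniform(-1.0, 1.0, size=(n_hidden, d))
    b = rng.uniform(-1.0, 1.0, size=n_hidden)
    model = ELMModel(
        input_weights=W,
        offsets=b,
        output_weights=np.zeros((n_hidden, P.shape[1])),
        activation=activation,
        n_hidden=n_hidden,
        seed=seed,
    )
    S = elm_hidden(model, X)
    V, *_ = np.linalg.lstsq(S, P, rcond=1e-12)
    model.output_weights = V
    return model


def elm_predict(m: ELMModel, X: np.ndarray) -> np.ndarray:
    """Network output O = S V for each sample; (L, m)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0:
        return np.empty((0, m.output_weights.shape[1]))
    return elm_hidden(m, X) @ m.output_weights


def elm_decide(
    scores: np.ndarray, positive_column: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Threshold one-hot outputs into labels + a continuous score.

    score = O[:, positive] - O[:, negative]; label 1 iff score > 0
    (exact ties go to 0).  Invariant to adding a constant to both
    columns.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[1] != 2:
        raise ShapeError(f"expected 2 output columns, got {scores.shape[1]}")
    negative_column = 1 - positive_column
    margin = scores[:, positive_column] - scores[:, negative_column]
    return (margin > 0).astype(int), margin
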