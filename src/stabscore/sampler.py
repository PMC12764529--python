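"""Discrete sequence optimization with the straight-through Gumbel trick.

The optimizer hallucinates a sequence by gradient descent on relaxed logits:

1. add Gumbel noise to the sequence logits ``I_soft`` and take a row-wise
   argmax, producing a one-hot sequence ``I_hard`` (Gumbel-max sampling:
   the argmax is a draw from the categorical softmax(I_soft / temperature));
2. evaluate the model's categorical cross-entropy loss at ``I_hard``;
3. backpropagate with a straight-through estimator,
   ``stop_gradient(I_hard − I_soft) + I_soft`` — the gradient of the loss at
   the hard point is applied directly to ``I_soft``, as if the argmax were
   the identity.  Only the input sequence is ever updated, never the model.

The loop runs until the best loss stops improving, and the best-so-far hard
sequence is returned.  A weighted sum of two models' losses plugs in
unchanged, mirroring joint optimization of a structure-prediction loss and
an inverse-folding loss over one shared sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .io import AA_ALPHABET, StabscoreError

__all__ = [
    "SequenceModel",
    "WeightedSumModel",
    "gumbel_argmax",
    "st_step",
    "optimize_sequence",
    "OptimizationResult",
]


@runtime_checkable
class SequenceModel(Protocol):
    """Differentiable loss over (L, A) sequence encodings.

    ``loss`` is a categorical cross-entropy (or any smooth energy) between
    the model's prediction and the current sequence; ``grad`` is its exact
    gradient, which must match central finite differences on toy models.
    """

    L: int
    A: int

    def loss(self, I: np.ndarray) -> float: ...

    def grad(self, I: np.ndarray) -> np.ndarray: ...


@dataclass
class WeightedSumModel:
    """Convex combination of losses sharing one sequence (joint optimization)."""

    models: Sequence[SequenceModel]
    weights: Sequence[float]

    def __post_init__(self) -> None:
        if len(self.models) != len(self.weights):
            raise StabscoreError("one weight per model required")
        shapes = {(m.L, m.A) for m in self.models}
        if len(shapes) != 1:
            raise StabscoreError("all models must share (L, A)")
        self.L, self.A = shapes.pop()

    def loss(self, I: np.ndarray) -> float:
        return float(sum(w * m.loss(I) for m, w in zip(self.models, self.weights)))

    def grad(self, I: np.ndarray) -> np.ndarray:
        return sum(w * m.grad(I) for m, w in zip(self.models, self.weights))


def gumbel_argmax(
    I_soft: np.ndarray, temperature: float = 1.0, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """One-hot row-wise argmax of ``I_soft + temperature · Gumbel`` noise.

    Temperature 0 disables the noise (plain argmax); ties break toward the
    lowest alphabet index.  With temperature 1 this is exact categorical
    sampling from softmax(I_soft) per row (the Gumbel-max trick).
    """
    I_soft = np.asarray(I_soft, dtype=float)
    if temperature < 0:
        raise StabscoreError("temperature must be >= 0")
    z = I_soft
    if temperature > 0:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        z = I_soft + temperature * rng.gumbel(size=I_soft.shape)
    hard = np.zeros_like(I_soft)
    hard[np.arange(I_soft.shape[0]), np.argmax(z, axis=1)] = 1.0
    return hard


def st_step(
    I_soft: np.ndarray,
    model: SequenceModel,
    lr: float = 0.1,
    temperature: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One straight-through update of the sequence logits.

    Forward: sample ``I_hard`` by Gumbel-argmax and evaluate the loss there.
    Backward: the straight-through composite ``stop_gradient(I_hard − I_soft)
    + I_soft`` has the identity Jacobian with respect to ``I_soft``, so the
    loss gradient at the hard point is applied to the soft logits unchanged.
    Returns ``(updated I_soft, I_hard, loss at I_hard)``.
    """
    if lr < 0:
        raise StabscoreError("learning rate must be >= 0")
    I_hard = gumbel_argmax(I_soft, temperature, seed)
    loss = model.loss(I_hard)
    if not np.isfinite(loss):
        raise StabscoreError(f"non-finite loss {loss!r} at straight-through point")
    grad = model.grad(I_hard)
    return I_soft - lr * grad, I_hard, float(loss)


@dataclass
class OptimizationResult:
    sequence: str
    best_loss: float
    best_one_hot: np.ndarray
    trace: list[float]  # best-so-far loss per iteration (non-increasing)
    n_iters: int


def optimize_sequence(
    model: SequenceModel,
    L: int | None = None,
    A: int | None = None,
    max_iters: int = 2000,
    patience: int = 50,
    tol: float = 1e-4,
    lr: float = 0.1,
    temperature: float = 1.0,
    seed: int = 0,
    alphabet: str | None = None,
) -> OptimizationResult:
    """Iterate :func:`st_step` from random logits, tracking the best sequence.

    ``I_soft`` is initialized from a seeded standard normal.  The loop stops
    when the best loss has not improved by more than ``tol`` for ``patience``
    iterations, or at ``max_iters``.  The best-so-far one-hot sequence is
    decoded with ``alphabet`` (default: the canonical 20 letters, or integer
    codes when A differs from 20 and no alphabet is given).
    """
    if max_iters < 1:
        raise StabscoreError("max_iters must be >= 1")
    L = L if L is not None else model.L
    A = A if A is not None else model.A
    rng = np.random.default_rng(seed)
    I_soft = rng.standard_normal((L, A))

    best_loss = np.inf
    best_hard = None
    trace: list[float] = []
    stall = 0
    n_iters = 0
    for _ in range(max_iters):
        n_iters += 1
        I_soft, I_hard, loss = st_step(I_soft, model, lr, temperature, rng)
        if loss < best_loss - tol:
            best_loss, best_hard, stall = loss, I_hard, 0
        else:
            if loss < best_loss:
                best_loss, best_hard = loss, I_hard
            stall += 1
        trace.append(best_loss)
        if stall >= patience:
            break

    if alphabet is None:
        alphabet = AA_ALPHABET if A == len(AA_ALPHABET) else None
    codes = np.argmax(best_hard, axis=1)
    if alphabet is not None:
        sequence = "".join(alphabet[c] for c in codes)
    else:
        sequence = "".join(str(c) for c in codes)
    return OptimizationResult(
        sequence=sequence,
        best_loss=float(best_loss),
        best_one_hot=best_hard,
        trace=trace,
        n_iters=n_iters,
    )
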