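"""Translational-distance score and the margin-based contrastive loss.

The chemical-balance constraint states that, in embedding space, the product
of a reaction is reached from its reactant by translating along the reaction's
transformation relation: ``R + T ≈ P``.  The residual norm ``‖R + T − P‖₂``
is the translational distance; candidates are ranked by its negation.

Training minimizes a margin loss over each minibatch: the mean positive
residual plus the mean hinge ``max(γ − ‖R_i + T_i − P_j‖₂, 0)`` over all
ordered unmatched pairs i ≠ j (the pair count |B|² − |B| is the normalizer,
so no external negative sampling takes place).  T_i always comes from
reaction i, including in the negative term.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .autodiff import Tensor

__all__ = [
    "TrainConfig",
    "translation_distance",
    "match_score",
    "batch_loss",
    "batch_loss_tensor",
    "total_loss",
]


@dataclass
class TrainConfig:
    """Optimization hyperparameters.

    margin: the hinge margin γ (> 0); 4 is the recommended setting.
    l2_lambda: strength λ of the L2 penalty on all trainable parameters.
    learning_rate: Adam step size (the tuning grid spans 1e-5 .. 1e-2).
    """

    margin: float = 4.0
    l2_lambda: float = 1e-5
    learning_rate: float = 1e-4
    batch_size: int = 32
    epochs: int = 20
    seed: int = 0

    def validate(self) -> None:
        if self.margin <= 0:
            raise ValueError("margin must be positive")
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be nonnegative")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be positive")


def translation_distance(r: np.ndarray, t: np.ndarray, p: np.ndarray) -> float:
    """Euclidean residual ‖R + T − P‖₂ of the chemical-balance constraint."""
    r, t, p = (np.asarray(x, dtype=np.float64) for x in (r, t, p))
    if not (r.shape == t.shape == p.shape):
        raise ValueError("R, T, P must share one dimension")
    return float(np.linalg.norm(r + t - p))


def match_score(r: np.ndarray, t: np.ndarray, p: np.ndarray) -> float:
    """Ranking score: negated translational distance (higher is better)."""
    return -translation_distance(r, t, p)


def batch_loss(
    batch: Sequence[tuple[np.ndarray, np.ndarray, np.ndarray]], margin: float
) -> float:
    """Margin-based contrastive loss of one minibatch (reference evaluation).

    Positive term: mean residual over matched triples.  Negative term: mean
    hinge over all ordered unmatched (R_i + T_i, P_j) pairs; a single-triple
    batch has no negative term.
    """
    n = len(batch)
    if n == 0:
        raise ValueError("batch must be non-empty")
    pos = np.mean([translation_distance(r, t, p) for r, t, p in batch])
    if n < 2:
        return float(pos)
    neg = 0.0
    for i, (r_i, t_i, _) in enumerate(batch):
        for j, (_, _, p_j) in enumerate(batch):
            if i == j:
                continue
            neg += max(margin - translation_distance(r_i, t_i, p_j), 0.0)
    return float(pos + neg / (n * n - n))


def batch_loss_tensor(r: Tensor, t: Tensor, p: Tensor, margin: float) -> Tensor:
    """Vectorized autodiff version of :func:`batch_loss` on (B, d) tensors."""
    n = r.shape[0]
    resid = r + t - p
    pos = (resid * resid).sum(axis=1).sqrt0().mean()
    if n < 2:
        return pos
    q = r + t
    q2 = (q * q).sum(axis=1, keepdims=True)  # (B,1)
    p2 = (p * p).sum(axis=1, keepdims=True)  # (B,1)
    d2 = q2 - 2.0 * (q @ p.T) + p2.T
    dist = d2.relu().sqrt0()
    mask = 1.0 - np.eye(n)
    hinge = (margin - dist).relu() * mask
    return pos + hinge.sum() * (1.0 / (n * n - n))


def total_loss(
    batch_loss_value: float | Tensor,
    params: Iterable[np.ndarray] | Iterable[Tensor],
    l2_lambda: float,
) -> float | Tensor:
    """Batch loss plus λ·‖Θ‖²_F over all trainable parameters."""
    reg = None
    for p in params:
        sq = (p * p).sum() if isinstance(p, Tensor) else float(np.sum(np.square(p)))
        reg = sq if reg is None else reg + sq
    if reg is None:
        return batch_loss_value
    return batch_loss_value + l2_lambda * reg
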