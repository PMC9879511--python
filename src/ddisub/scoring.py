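"""Per-relation bilinear scoring, cross-entropy loss, key-pair extraction.

A typed interaction tuple (d_x, d_y, r) is scored as

    P(d_x, d_y, r) = sigmoid( g_x^T  M_r  g_y )

with one learnable h x h matrix M_r per interaction type.  M_r is not
constrained to be symmetric, so the score is direction-aware:
P(x, y, r) != P(y, x, r) in general (an optional flag symmetrizes via
(M_r + M_r^T)/2).  Training minimizes binary cross-entropy over labeled
tuples; probabilities are clamped to [eps, 1-eps] before the logs.

The L x L matrix of pairwise substructure scores
``S_ij = ghat_x^(i)^T M_r ghat_y^(j)`` localizes the decision: its argmax
(h, t) names the layer pair — hence receptive-field radii — most
responsible for the predicted interaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Var, gather, glorot

__all__ = ["RelationMatrices", "PredictionOutput", "score", "bce_loss",
           "bce_loss_logits", "pairwise_scores", "key_substructure_indices",
           "EPS"]

EPS = 1e-7  # probability clamp before logs


@dataclass
class RelationMatrices:
    """One learnable bilinear matrix per interaction type."""

    M: Var  # (n_relations, h, h)
    symmetrize: bool = False

    @classmethod
    def create(cls, rng: np.random.Generator, n_relations: int, hidden: int,
               symmetrize: bool = False) -> "RelationMatrices":
        return cls(M=glorot(rng, n_relations, hidden, hidden), symmetrize=symmetrize)

    @property
    def n_relations(self) -> int:
        return self.M.shape[0]

    def matrix(self, r: int) -> Var:
        if not 0 <= r < self.n_relations:
            raise KeyError(f"unknown relation id {r} (have 0..{self.n_relations - 1})")
        m = gather(self.M, np.array([r])).reshape(self.M.shape[1], self.M.shape[2])
        if self.symmetrize:
            m = (m + m.T) * 0.5
        return m

    def parameters(self) -> list[Var]:
        return [self.M]


@dataclass
class PredictionOutput:
    """Score of one tuple plus its interpretability traces."""

    logit: float
    probability: float
    key_indices: tuple[int, int] | None = None  # 1-based (h, t)
    pairwise: np.ndarray | None = None  # (L, L) substructure score matrix


def score(g_x: Var, g_y: Var, r: int, relations: RelationMatrices) -> Var:
    """Tuple probability ``sigmoid(g_x^T M_r g_y)`` as a scalar Var."""
    m = relations.matrix(r)
    logit = (g_x @ m) @ g_y
    return logit.sigmoid()


def bce_loss(probs: Var, labels: np.ndarray) -> Var:
    """Mean binary cross-entropy with probability clamping.

    ``probs`` is a 1-D Var of predicted probabilities, ``labels`` the 0/1
    targets.  Raises on an empty batch (the mean is undefined).
    """
    labels = np.asarray(labels, dtype=np.float64)
    if labels.size == 0:
        raise ValueError("empty batch")
    p = probs.clip(EPS, 1.0 - EPS)
    y = Var(labels)
    ll = y * p.log() + (1.0 - y) * (1.0 - p).log()
    return -ll.mean()


def bce_loss_logits(logits: Var, labels: np.ndarray) -> Var:
    """Mean binary cross-entropy computed from logits.

    Algebraically ``bce_loss(sigmoid(logits), labels)`` but stable for
    large |logit| via the softplus identity
    ``-log sigmoid(z) = softplus(-z)``; used by the training loop so
    saturated predictions keep a useful gradient.
    """
    labels = np.asarray(labels, dtype=np.float64)
    if labels.size == 0:
        raise ValueError("empty batch")
    y = Var(labels)
    # softplus(z) = max(z, 0) + log1p(exp(-|z|)); expressed through the
    # tape as relu(z) + log(1 + exp(-|z|)) with |z| built from relu pairs
    z = logits
    absz = z.relu() + (-z).relu()
    softplus = z.relu() + (1.0 + (-absz).exp()).log()
    ll = y * (z - softplus) + (1.0 - y) * (-softplus)
    return -ll.mean()


def pairwise_scores(ghat_x: Var, ghat_y: Var, r: int,
                    relations: RelationMatrices) -> Var:
    """L x L matrix ``S_ij = ghat_x^(i)^T M_r ghat_y^(j)``."""
    m = relations.matrix(r)
    return (ghat_x @ m) @ ghat_y.T


def key_substructure_indices(scores: np.ndarray, k: int = 1) -> list[tuple[int, int]]:
    """Top-k entries of the pairwise score matrix, 1-based (h, t) pairs.

    Ties are broken toward the lexicographically smallest (h, t).  The
    returned layer indices double as receptive-field radii of the
    substructures driving the prediction.
    """
    scores = np.asarray(scores)
    L1, L2 = scores.shape
    if k > L1 * L2:
        raise ValueError(f"k={k} exceeds the {L1}x{L2} score matrix")
    flat = [(-scores[i, j], i, j) for i in range(L1) for j in range(L2)]
    flat.sort()
    return [(i + 1, j + 1) for _, i, j in flat[:k]]
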