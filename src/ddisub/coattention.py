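"""Layer-wise substructure stacks and cross-drug co-attention.

L independent SA-DMPNN blocks are stacked (a "Multi-GNN"): block l consumes
block l-1's node features (raw 42-dim atom vectors at l=1) together with the
original bond features, so layer l sees substructures of receptive-field
radius up to l*T bonds.  Each layer is pooled into a substructure vector

    g^(l) = sum_i beta_i h_i^(l)

where beta_i is a per-layer node importance (one-layer graph convolution on
the atom graph, softmaxed over the molecule's atoms — scores are used as
weights, no nodes are dropped).

Two drugs are coupled through an L x L co-attention map

    gamma_ij = b^T tanh(W_x g_x^(i) + W_y g_y^(j))

left unnormalized by default (an optional row-wise softmax is available).
The reweighted stacks satisfy the row-sum identity
``ghat_x^(i) = (sum_j gamma_ij) * g_x^(i)`` and sum to the final graph-level
representations g_x, g_y.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Var, gather, glorot, segment_sum, softmax, stack
from .dmpnn import EncoderParams, EncoderTrace, encode
from .molgraph import ATOM_FDIM, MolecularGraph

__all__ = ["MultiGNNParams", "SubstructureStack", "CoAttentionMap",
           "layer_representations", "co_attention", "reweight_and_pool",
           "couple_drugs"]


@dataclass
class MultiGNNParams:
    """Parameters of the L-layer stack plus the co-attention coupling."""

    blocks: list[EncoderParams]
    node_scorers: list[Var]  # per layer, shape (h,)
    b_co: Var  # (h,)
    W_x: Var  # (h, h)
    W_y: Var  # (h, h)
    softmax_gamma: bool = False

    @classmethod
    def create(cls, rng: np.random.Generator, hidden: int, T: int, L: int,
               in_dim: int = ATOM_FDIM, recompute_beta: bool = True,
               softmax_gamma: bool = False) -> "MultiGNNParams":
        if L < 1:
            raise ValueError("L must be >= 1")
        blocks = [
            EncoderParams.create(
                rng, hidden, T,
                in_dim=in_dim if l == 0 else hidden,
                recompute_beta=recompute_beta,
            )
            for l in range(L)
        ]
        return cls(
            blocks=blocks,
            node_scorers=[glorot(rng, hidden) for _ in range(L)],
            b_co=glorot(rng, hidden),
            W_x=glorot(rng, hidden, hidden),
            W_y=glorot(rng, hidden, hidden),
            softmax_gamma=softmax_gamma,
        )

    @property
    def L(self) -> int:
        return len(self.blocks)

    @property
    def hidden(self) -> int:
        return self.blocks[0].hidden

    def parameters(self) -> list[Var]:
        ps: list[Var] = []
        for b in self.blocks:
            ps.extend(b.parameters())
        ps.extend(self.node_scorers)
        ps.extend([self.b_co, self.W_x, self.W_y])
        return ps


@dataclass
class SubstructureStack:
    """Per-layer node features, node importances and pooled vectors."""

    node_features: list[Var]  # L entries of shape (n, h)
    node_importance: list[Var]  # L entries of shape (n,)
    g: list[Var]  # L entries of shape (h,)
    traces: list[EncoderTrace] = field(default_factory=list)

    @property
    def L(self) -> int:
        return len(self.g)

    def g_matrix(self) -> Var:
        return stack(self.g)  # (L, h)


@dataclass
class CoAttentionMap:
    """The L x L interaction map and everything derived from it."""

    gamma: Var  # (L, L)
    ghat_x: Var  # (L, h) reweighted stack of drug x
    ghat_y: Var  # (L, h)
    g_x: Var  # (h,)
    g_y: Var  # (h,)


def _node_importance(graph: MolecularGraph, feats: Var, scorer: Var) -> Var:
    """Softmax over atoms of a one-layer atom-graph convolution score."""
    neigh = segment_sum(gather(feats, graph.bond_src), graph.bond_dst, graph.n_atoms)
    scores = (feats + neigh) @ scorer  # (n,)
    return softmax(scores, axis=0)


def layer_representations(graph: MolecularGraph, params: MultiGNNParams,
                          keep_traces: bool = False) -> SubstructureStack:
    """Run all L blocks on one drug and pool each layer.

    Layer l's atom input is layer l-1's node features; bond features are
    reused unchanged at every layer.
    """
    stack_ = SubstructureStack(node_features=[], node_importance=[], g=[])
    x: Var | None = None
    for block, scorer in zip(params.blocks, params.node_scorers):
        feats, trace = encode(graph, block, x_atoms=x, return_trace=True)
        beta = _node_importance(graph, feats, scorer)
        g_l = (feats * beta.reshape(-1, 1)).sum(axis=0)
        stack_.node_features.append(feats)
        stack_.node_importance.append(beta)
        stack_.g.append(g_l)
        if keep_traces:
            stack_.traces.append(trace)
        x = feats
    return stack_


def co_attention(stack_x: SubstructureStack, stack_y: SubstructureStack,
                 params: MultiGNNParams) -> Var:
    """The L x L map ``gamma_ij = b^T tanh(W_x g_x^(i) + W_y g_y^(j))``."""
    if stack_x.L != stack_y.L:
        raise ValueError("substructure stacks have different depths")
    px = stack_x.g_matrix() @ params.W_x.T  # (L, h)
    py = stack_y.g_matrix() @ params.W_y.T
    L, h = px.shape
    pairwise = (px.reshape(L, 1, h) + py.reshape(1, L, h)).tanh()
    gamma = pairwise @ params.b_co  # (L, L)
    if params.softmax_gamma:
        gamma = softmax(gamma, axis=1)
    return gamma


def reweight_and_pool(stack_x: SubstructureStack, stack_y: SubstructureStack,
                      gamma: Var) -> CoAttentionMap:
    """Reweight the stacks by gamma row/column sums and pool to g_x, g_y."""
    gx = stack_x.g_matrix()  # (L, h)
    gy = stack_y.g_matrix()
    row = gamma.sum(axis=1)  # (L,)
    col = gamma.sum(axis=0)
    ghat_x = gx * row.reshape(-1, 1)
    ghat_y = gy * col.reshape(-1, 1)
    return CoAttentionMap(
        gamma=gamma,
        ghat_x=ghat_x,
        ghat_y=ghat_y,
        g_x=ghat_x.sum(axis=0),
        g_y=ghat_y.sum(axis=0),
    )


def couple_drugs(stack_x: SubstructureStack, stack_y: SubstructureStack,
                 params: MultiGNNParams) -> CoAttentionMap:
    """Convenience composition of :func:`co_attention` and pooling."""
    return reweight_and_pool(stack_x, stack_y, co_attention(stack_x, stack_y, params))
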