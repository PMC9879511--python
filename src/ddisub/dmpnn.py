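"""Directed message passing with substructure attention (SA-DMPNN).

Hidden state lives on *directed bonds*.  For bond i->j:

.. math::

    h_{ij}^{(0)} &= W_i x_i + W_j x_j + W_{ij} x_{ij} \\
    h_{ij}^{(t)} &= \\mathrm{ReLU}\\Big(h_{ij}^{(0)}
                    + W_m \\sum_{k \\in N(i) \\setminus \\{j\\}}
                    h_{ki}^{(t-1)}\\Big)

i.e. the classic directed-MPNN update that excludes the reverse bond, so
messages never immediately flow back where they came from.  On top of this
sit two attention mechanisms:

* **bond importance** beta: a one-layer graph convolution over the bond
  line graph (two directed bonds are adjacent when they share an atom)
  scores each bond; scores are softmax-normalized over the incoming bonds
  of each destination atom, making the per-atom message
  ``m_i = sum_j beta_ji h_ji`` a convex combination;
* **step (substructure) attention** alpha: each step's graph summary
  ``g_t = sum_i m_i`` is scored by ``e_t = <w_t, tanh(W g_t + b)>`` and
  softmaxed over steps, so the encoder weighs receptive-field radii
  (substructure sizes) against each other.

Final bond features are the alpha-weighted sum over steps; node features
aggregate incoming final bond features plus a learned projection of the raw
atom vector through a one-hidden-layer MLP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Var, gather, glorot, segment_softmax, segment_sum, stack
from .molgraph import ATOM_FDIM, BOND_FDIM, MolecularGraph

__all__ = ["EncoderParams", "EncoderTrace", "encode"]


@dataclass
class EncoderParams:
    """Learnable tensors of one SA-DMPNN block.

    ``w_step`` is per-step (shape (T, h)); the bond update matrix ``W_m``
    and the attention projection ``W_att``/``b_att`` are shared across
    steps.  ``recompute_beta`` controls whether bond importances are
    refreshed from the current bond states at every step (default) or
    computed once from the initial states.
    """

    W_i: Var
    W_j: Var
    W_ij: Var
    W_m: Var
    W_0: Var  # input projection for the node readout
    w_bond: Var  # line-graph convolution scorer, shape (h,)
    w_step: Var  # (T, h)
    W_att: Var  # (h, h)
    b_att: Var  # (h,)
    mlp_W1: Var
    mlp_b1: Var
    mlp_W2: Var
    mlp_b2: Var
    T: int
    recompute_beta: bool = True

    @classmethod
    def create(cls, rng: np.random.Generator, hidden: int, T: int,
               in_dim: int = ATOM_FDIM, bond_dim: int = BOND_FDIM,
               recompute_beta: bool = True) -> "EncoderParams":
        if T < 1:
            raise ValueError("T must be >= 1")
        h = hidden
        zeros = lambda *s: Var(np.zeros(s), requires_grad=True)
        return cls(
            W_i=glorot(rng, h, in_dim),
            W_j=glorot(rng, h, in_dim),
            W_ij=glorot(rng, h, bond_dim),
            W_m=glorot(rng, h, h),
            W_0=glorot(rng, h, in_dim),
            w_bond=glorot(rng, h),
            w_step=glorot(rng, T, h),
            W_att=glorot(rng, h, h),
            b_att=zeros(h),
            mlp_W1=glorot(rng, h, h),
            mlp_b1=zeros(h),
            mlp_W2=glorot(rng, h, h),
            mlp_b2=zeros(h),
            T=T,
            recompute_beta=recompute_beta,
        )

    @property
    def hidden(self) -> int:
        return self.W_m.shape[0]

    def parameters(self) -> list[Var]:
        return [self.W_i, self.W_j, self.W_ij, self.W_m, self.W_0, self.w_bond,
                self.w_step, self.W_att, self.b_att,
                self.mlp_W1, self.mlp_b1, self.mlp_W2, self.mlp_b2]


@dataclass
class EncoderTrace:
    """Intermediates of one encoder run, kept for tests and explanations."""

    bond_states: list[Var] = field(default_factory=list)  # index t = 0..T
    beta: list[Var] = field(default_factory=list)  # per step 1..T
    m_node: list[Var] = field(default_factory=list)
    g_step: list[Var] = field(default_factory=list)
    e_step: Var | None = None
    alpha: Var | None = None
    final_bond: Var | None = None


def init_bond_states(graph: MolecularGraph, params: EncoderParams,
                     x_atoms: Var | None = None) -> Var:
    """Initial directed-bond states ``h0 = W_i x_i + W_j x_j + W_ij x_ij``."""
    x = Var(graph.atom_features) if x_atoms is None else x_atoms
    if params.W_i.shape[1] != x.shape[1]:
        raise ValueError(
            f"atom feature dim {x.shape[1]} != encoder input dim {params.W_i.shape[1]}"
        )
    xb = Var(graph.bond_features)
    hi = gather(x @ params.W_i.T, graph.bond_src)
    hj = gather(x @ params.W_j.T, graph.bond_dst)
    return hi + hj + xb @ params.W_ij.T


def _linegraph_neighbor_sum(graph: MolecularGraph, states: Var) -> Var:
    """Sum of states over line-graph neighbors (bonds sharing an atom).

    For bond k = (i -> j) every other directed bond incident to i or j is a
    neighbor.  ``touch[v]`` sums states of all bonds incident to v; bond k
    itself is incident to both endpoints (subtract twice), its reverse also
    to both (counted twice, keep once).
    """
    n = graph.n_atoms
    touch = segment_sum(states, graph.bond_src, n) + segment_sum(states, graph.bond_dst, n)
    total = gather(touch, graph.bond_src) + gather(touch, graph.bond_dst)
    rev = gather(states, graph.reverse_index)
    return total - 2.0 * states - rev


def compute_bond_importance(graph: MolecularGraph, states: Var,
                            params: EncoderParams) -> Var:
    """Per-bond importance beta via a line-graph convolution + softmax.

    Raw score of bond k is ``<w_bond, h_k + sum of line-graph neighbors>``
    (self-loop included); the softmax runs over the incoming-bond set of
    each destination atom, so ``sum_{j in N(i)} beta_ji = 1`` for every
    atom i with at least one bond.
    """
    agg = states + _linegraph_neighbor_sum(graph, states)
    scores = agg @ params.w_bond
    return segment_softmax(scores, graph.bond_dst, graph.n_atoms)


def update_bond_states(graph: MolecularGraph, states: Var, h0: Var,
                       params: EncoderParams) -> Var:
    """Directed-MPNN bond update, excluding the reverse bond.

    For bond i->j the message is the sum of states of bonds k->i with
    k != j, so information never immediately reflects back.
    """
    incoming = segment_sum(states, graph.bond_dst, graph.n_atoms)
    neigh = gather(incoming, graph.bond_src) - gather(states, graph.reverse_index)
    return (h0 + neigh @ params.W_m.T).relu()


def message_step(graph: MolecularGraph, states: Var, beta: Var) -> tuple[Var, Var]:
    """Beta-weighted node messages and the per-step graph summary.

    ``m_i = sum_{j in N(i)} beta_ji h_ji`` (a convex combination thanks to
    the per-atom softmax over incoming bonds); ``g = sum_i m_i``.
    """
    weighted = states * beta.reshape(-1, 1)
    m_node = segment_sum(weighted, graph.bond_dst, graph.n_atoms)
    g = m_node.sum(axis=0)
    return m_node, g


def substructure_attention(g_steps: list[Var], params: EncoderParams) -> tuple[Var, Var]:
    """Score each step's graph summary and softmax over steps."""
    gs = stack(g_steps)  # (T, h)
    proj = (gs @ params.W_att.T + params.b_att).tanh()
    e = (params.w_step * proj).sum(axis=1)  # (T,)
    shift = Var(e.data.max())
    ex = (e - shift).exp()
    alpha = ex / ex.sum()
    return e, alpha


def aggregate_bond_states(bond_states: list[Var], alpha: Var) -> Var:
    """Alpha-weighted sum of bond states over steps 1..T."""
    stacked = stack(bond_states)  # (T, B, h)
    return (stacked * alpha.reshape(-1, 1, 1)).sum(axis=0)


def finalize_node_features(graph: MolecularGraph, final_bond: Var,
                           params: EncoderParams, x_atoms: Var | None = None) -> Var:
    """Node readout: MLP over projected input plus incoming bond features."""
    x = Var(graph.atom_features) if x_atoms is None else x_atoms
    agg = x @ params.W_0.T + segment_sum(final_bond, graph.bond_dst, graph.n_atoms)
    hidden = (agg @ params.mlp_W1.T + params.mlp_b1).relu()
    return hidden @ params.mlp_W2.T + params.mlp_b2


def encode(graph: MolecularGraph, params: EncoderParams,
           x_atoms: Var | None = None,
           return_trace: bool = False) -> Var | tuple[Var, EncoderTrace]:
    """Run the full SA-DMPNN block and return per-atom features (n, h).

    ``x_atoms`` overrides the raw atom features (used when blocks are
    stacked and layer l consumes layer l-1 node features).
    """
    trace = EncoderTrace()
    h0 = init_bond_states(graph, params, x_atoms)
    trace.bond_states.append(h0)
    states = h0
    beta = None if params.recompute_beta else compute_bond_importance(graph, h0, params)
    for t in range(1, params.T + 1):
        states = update_bond_states(graph, states, h0, params)
        if params.recompute_beta:
            beta = compute_bond_importance(graph, states, params)
        m_node, g = message_step(graph, states, beta)
        trace.bond_states.append(states)
        trace.beta.append(beta)
        trace.m_node.append(m_node)
        trace.g_step.append(g)
    e, alpha = substructure_attention(trace.g_step, params)
    trace.e_step, trace.alpha = e, alpha
    final_bond = aggregate_bond_states(trace.bond_states[1:], alpha)
    trace.final_bond = final_bond
    node_features = finalize_node_features(graph, final_bond, params, x_atoms)
    if return_trace:
        return node_features, trace
    return node_features
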