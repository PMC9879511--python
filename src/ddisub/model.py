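"""The full dual-GNN model: shared Multi-GNN encoder + co-attention + bilinear scoring.

Both drugs of a tuple are encoded by the *same* L-layer stack; only the
co-attention matrices W_x / W_y and the per-relation bilinear matrices
distinguish the two sides.  ``forward_batch`` encodes every distinct drug
in a batch exactly once — drug representations are shared across all tuples
that mention the drug, and gradients accumulate through that shared
subgraph of the tape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .autodiff import Var, gather, softmax, stack
from .coattention import (MultiGNNParams, SubstructureStack, couple_drugs,
                          layer_representations)
from .molgraph import DDITuple, MolecularGraph, parse_smiles
from .scoring import (PredictionOutput, RelationMatrices, key_substructure_indices,
                      pairwise_scores)

__all__ = ["ModelConfig", "DDIModel"]


@dataclass
class ModelConfig:
    """Architecture hyperparameters (defaults follow the reference setting)."""

    hidden: int = 64
    T: int = 3
    L: int = 3
    n_relations: int = 1
    recompute_beta: bool = True
    softmax_gamma: bool = False
    symmetrize_relations: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


class DDIModel:
    """Bundles all learnable tensors and the tuple-scoring pipeline."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.encoder = MultiGNNParams.create(
            rng, config.hidden, config.T, config.L,
            recompute_beta=config.recompute_beta,
            softmax_gamma=config.softmax_gamma,
        )
        self.relations = RelationMatrices.create(
            rng, config.n_relations, config.hidden,
            symmetrize=config.symmetrize_relations,
        )
        self._graph_cache: dict[str, MolecularGraph] = {}

    # -- parameters -------------------------------------------------------

    def parameters(self) -> list[Var]:
        return self.encoder.parameters() + self.relations.parameters()

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("checkpoint does not match model architecture")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(
                    f"checkpoint tensor shape {a.shape} != model shape {p.data.shape}"
                )
            p.data = np.array(a, dtype=np.float64)

    # -- graphs -----------------------------------------------------------

    def graph_for(self, smiles: str) -> MolecularGraph:
        if smiles not in self._graph_cache:
            self._graph_cache[smiles] = parse_smiles(smiles)
        return self._graph_cache[smiles]

    # -- forward ----------------------------------------------------------

    def encode_drug(self, graph: MolecularGraph, keep_traces: bool = False) -> SubstructureStack:
        return layer_representations(graph, self.encoder, keep_traces=keep_traces)

    def forward_pair(self, graph_x: MolecularGraph, graph_y: MolecularGraph,
                     r: int, keep_traces: bool = False):
        """Full pipeline on one tuple; returns (logit Var, stacks, co-attention map)."""
        stack_x = self.encode_drug(graph_x, keep_traces=keep_traces)
        stack_y = self.encode_drug(graph_y, keep_traces=keep_traces)
        comap = couple_drugs(stack_x, stack_y, self.encoder)
        m = self.relations.matrix(r)
        logit = (comap.g_x @ m) @ comap.g_y
        return logit, stack_x, stack_y, comap

    def predict(self, graph_x: MolecularGraph, graph_y: MolecularGraph,
                r: int, k: int = 1) -> PredictionOutput:
        """Score one tuple and extract the key substructure layer pair."""
        logit, _sx, _sy, comap = self.forward_pair(graph_x, graph_y, r)
        pw = pairwise_scores(comap.ghat_x, comap.ghat_y, r, self.relations)
        keys = key_substructure_indices(pw.data, k=k)
        prob = logit.sigmoid()
        return PredictionOutput(
            logit=float(logit.data),
            probability=float(prob.data),
            key_indices=keys[0],
            pairwise=pw.data.copy(),
        )

    def forward_batch(self, graphs: dict[str, MolecularGraph],
                      tuples: Iterable[DDITuple]) -> Var:
        """Logits for a batch of tuples as a 1-D Var (sigmoid gives probs).

        Every distinct drug id is encoded once; co-attention and scoring
        are vectorized across the batch with batched matrix products.
        """
        tuples = list(tuples)
        ids = sorted({t.drug_x for t in tuples} | {t.drug_y for t in tuples})
        index = {d: i for i, d in enumerate(ids)}
        stacks = [self.encode_drug(graphs[d]).g_matrix() for d in ids]  # (L, h) each
        G = stack(stacks)  # (D, L, h)
        PX = G @ self.encoder.W_x.T  # (D, L, h)
        PY = G @ self.encoder.W_y.T

        xi = np.array([index[t.drug_x] for t in tuples])
        yi = np.array([index[t.drug_y] for t in tuples])
        ri = np.array([t.relation for t in tuples])
        B = len(tuples)
        L = self.encoder.L
        h = self.encoder.hidden
        px = gather(PX, xi)  # (B, L, h)
        py = gather(PY, yi)
        gamma = ((px.reshape(B, L, 1, h) + py.reshape(B, 1, L, h)).tanh()
                 @ self.encoder.b_co)  # (B, L, L)
        if self.encoder.softmax_gamma:
            gamma = softmax(gamma, axis=2)
        gx_stack = gather(G, xi)  # (B, L, h)
        gy_stack = gather(G, yi)
        g_x = (gx_stack * gamma.sum(axis=2).reshape(B, L, 1)).sum(axis=1)  # (B, h)
        g_y = (gy_stack * gamma.sum(axis=1).reshape(B, L, 1)).sum(axis=1)
        M = gather(self.relations.M, ri)  # (B, h, h)
        if self.relations.symmetrize:
            M = (M + M.swapaxes(-1, -2)) * 0.5
        return (g_x.reshape(B, 1, h) @ M @ g_y.reshape(B, h, 1)).reshape(B)

    # -- checkpointing ----------------------------------------------------

    def save(self, path) -> None:
        """Write weights + config to an ``.npz`` checkpoint."""
        arrays = {f"p{i}": a for i, a in enumerate(self.state_arrays())}
        cfg = self.config.to_dict()
        np.savez(path, _config=np.array([repr(cfg)]), **arrays)

    @classmethod
    def load(cls, path) -> "DDIModel":
        data = np.load(path, allow_pickle=False)
        import ast

        cfg = ModelConfig(**ast.literal_eval(str(data["_config"][0])))
        model = cls(cfg)
        arrays = [data[f"p{i}"] for i in range(len(model.parameters()))]
        model.load_state_arrays(arrays)
        return model
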