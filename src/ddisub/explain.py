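"""Post-hoc explanations: atom similarity maps and key-substructure annotation.

Two complementary views of what the trained encoder learned:

* **Atom similarity** — the Pearson correlation between final-layer node
  feature vectors of every atom pair.  As training progresses these
  matrices organize into blocks that mirror the molecule's functional
  regions.
* **Key substructures** — for a scored tuple, the argmax layer pair (h, t)
  of the pairwise substructure score matrix names one layer per drug; that
  layer's node-importance weights beta_i rank the atoms, the top-3 become
  substructure centers, and the layer index is read as a receptive-field
  radius: every atom within graph distance <= radius of a center belongs to
  the highlighted substructure.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .model import DDIModel
from .molgraph import MolecularGraph
from .scoring import key_substructure_indices, pairwise_scores

__all__ = ["atom_similarity", "SubstructureAnnotation", "graph_distances",
           "annotate_key_substructures", "explain_tuple"]


def atom_similarity(node_features: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix between atoms' feature vectors.

    Zero-variance (constant) feature vectors have undefined correlation;
    by convention their off-diagonal similarities are 0 and the diagonal
    stays 1.
    """
    x = np.asarray(node_features, dtype=np.float64)
    n, d = x.shape
    if n < 2:
        raise ValueError("need at least 2 atoms for a similarity matrix")
    if d < 2:
        raise ValueError("need feature dimension >= 2")
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    degenerate = norms < 1e-12
    safe = np.where(degenerate, 1.0, norms)
    unit = centered / safe[:, None]
    sim = unit @ unit.T
    sim[degenerate, :] = 0.0
    sim[:, degenerate] = 0.0
    np.fill_diagonal(sim, 1.0)
    return np.clip(sim, -1.0, 1.0)


def graph_distances(graph: MolecularGraph, sources: list[int]) -> np.ndarray:
    """Shortest bond-count distance from the nearest source atom (BFS)."""
    dist = np.full(graph.n_atoms, np.inf)
    q = deque()
    for s in sources:
        dist[s] = 0
        q.append(s)
    adj = [[] for _ in range(graph.n_atoms)]
    for s, t in zip(graph.bond_src, graph.bond_dst):
        adj[s].append(t)
    while q:
        u = q.popleft()
        for v in adj[u]:
            if dist[v] > dist[u] + 1:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


@dataclass
class SubstructureAnnotation:
    """Atom sets describing one drug's key substructure."""

    layer: int  # 1-based layer index == receptive-field radius
    center_atoms: list[int]  # top-3 atoms by node importance
    member_atoms: list[int]  # atoms within graph distance <= layer of a center
    beta: np.ndarray  # node importance of the selected layer

    def to_dict(self) -> dict:
        return {"layer": self.layer, "center_atoms": self.center_atoms,
                "member_atoms": self.member_atoms, "beta": self.beta.tolist()}


def _annotate(graph: MolecularGraph, beta: np.ndarray, layer: int,
              n_centers: int = 3) -> SubstructureAnnotation:
    if graph.n_atoms < 1:
        raise ValueError("empty molecule")
    order = np.argsort(-beta, kind="stable")
    centers = [int(i) for i in order[: min(n_centers, graph.n_atoms)]]
    dist = graph_distances(graph, centers)
    members = [int(i) for i in np.flatnonzero(dist <= layer)]
    return SubstructureAnnotation(layer=layer, center_atoms=centers,
                                  member_atoms=members, beta=beta)


def annotate_key_substructures(graph_x: MolecularGraph, graph_y: MolecularGraph,
                               stack_x, stack_y, comap, r: int, relations,
                               k: int = 1, n_centers: int = 3
                               ) -> list[tuple[SubstructureAnnotation, SubstructureAnnotation]]:
    """Annotate the top-k key substructure pairs of a scored tuple.

    Returns one (annotation_x, annotation_y) pair per key layer pair
    (h, t): drug x is annotated from layer h, drug y from layer t, each
    with radius equal to its layer index.
    """
    pw = pairwise_scores(comap.ghat_x, comap.ghat_y, r, relations)
    pairs = key_substructure_indices(pw.data, k=k)
    out = []
    for h, t in pairs:
        ann_x = _annotate(graph_x, stack_x.node_importance[h - 1].data, h, n_centers)
        ann_y = _annotate(graph_y, stack_y.node_importance[t - 1].data, t, n_centers)
        out.append((ann_x, ann_y))
    return out


def explain_tuple(model: DDIModel, graph_x: MolecularGraph,
                  graph_y: MolecularGraph, r: int, k: int = 1) -> dict:
    """Full explanation bundle for one tuple, JSON-serializable.

    Contains the probability, the co-attention map gamma, the pairwise
    substructure scores with their argmax layer pair, per-drug annotations
    and final-layer atom similarity matrices.
    """
    from .coattention import couple_drugs

    stack_x = model.encode_drug(graph_x, keep_traces=True)
    stack_y = model.encode_drug(graph_y, keep_traces=True)
    comap = couple_drugs(stack_x, stack_y, model.encoder)
    m = model.relations.matrix(r)
    logit = (comap.g_x @ m) @ comap.g_y
    pw = pairwise_scores(comap.ghat_x, comap.ghat_y, r, model.relations)
    annotations = annotate_key_substructures(
        graph_x, graph_y, stack_x, stack_y, comap, r, model.relations, k=k)
    prob = float(logit.sigmoid().data)
    return {
        "probability": prob,
        "logit": float(logit.data),
        "gamma": comap.gamma.data.tolist(),
        "pairwise_scores": pw.data.tolist(),
        "key_pairs": [[a.layer, b.layer] for a, b in annotations],
        "annotation_x": [a.to_dict() for a, _ in annotations],
        "annotation_y": [b.to_dict() for _, b in annotations],
        "atom_similarity_x": atom_similarity(stack_x.node_features[-1].data).tolist(),
        "atom_similarity_y": atom_similarity(stack_y.node_features[-1].data).tolist(),
    }
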