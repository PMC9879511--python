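"""Shared fixtures: tiny hand-built graphs and parameter factories."""

import numpy as np
import pytest

from ddisub.dmpnn import EncoderParams
from ddisub.molgraph import ATOM_FDIM, BOND_FDIM, MolecularGraph


def path_graph(atom_features: np.ndarray, bond_features: np.ndarray | None = None) -> MolecularGraph:
    """A chain molecule with fully controlled feature matrices.

    ``atom_features`` is (n, d); bond k of the chain joins atoms k and k+1.
    """
    n = atom_features.shape[0]
    if bond_features is None:
        bond_features = np.tile(np.eye(BOND_FDIM)[0], (n - 1, 1))
    src, dst, feats = [], [], []
    for k in range(n - 1):
        src += [k, k + 1]
        dst += [k + 1, k]
        feats += [bond_features[k], bond_features[k]]
    m = len(src)
    return MolecularGraph(
        atom_features=np.asarray(atom_features, dtype=float),
        bond_features=np.asarray(feats, dtype=float).reshape(m, BOND_FDIM),
        bond_src=np.array(src, dtype=np.intp),
        bond_dst=np.array(dst, dtype=np.intp),
        reverse_index=np.arange(m) ^ 1,
        smiles="",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_params(rng):
    """Small encoder on raw 42-dim atom features, h=5, T=2."""
    return EncoderParams.create(rng, hidden=5, T=2)


def random_path_graph(rng, n_atoms: int, d: int = ATOM_FDIM) -> MolecularGraph:
    return path_graph(rng.normal(size=(n_atoms, d)),
                      rng.normal(size=(max(n_atoms - 1, 0), BOND_FDIM)))
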