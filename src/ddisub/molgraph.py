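"""SMILES parsing, atom/bond featurization, and drug/DDI table I/O.

A drug is an attributed molecular graph: atoms are nodes, every chemical
bond contributes two *directed* bonds (i->j and j->i).  Atom vectors are
42-dimensional and bond vectors 6-dimensional, built from fixed one-hot
blocks plus integer fields:

=================  ====================================================  ====
atom block         values                                                size
=================  ====================================================  ====
element            B,C,N,O,F,Si,P,S,Cl,As,Se,Br,Te,I,At,meta             16
degree             number of heavy-atom covalent bonds, 0..10            11
hybridization      sp, sp2, sp3, sp3d, sp3d2                              5
implicit valence   0..6                                                   7
radical electrons  integer count                                          1
formal charge      integer                                                1
aromatic           flag                                                   1
=================  ====================================================  ====

Bond vectors: bond type one-hot (single,double,triple,aromatic), conjugated
flag, ring flag.  Elements outside the 16-slot list fall into the ``meta``
slot; hybridization states outside the five listed yield an all-zero block;
degree/valence beyond the table range clamp to the last slot (warnings are
logged for the latter two).  Hydrogens are implicit and never appear as
nodes; stereochemistry and isotopes are ignored.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdmolops

log = logging.getLogger(__name__)

ELEMENTS = ["B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "As", "Se", "Br", "Te", "I", "At"]
HYBRIDIZATIONS = [
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
]
BOND_TYPES = [
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
]

ATOM_FDIM = 42  # 16 + 11 + 5 + 7 + 1 + 1 + 1
BOND_FDIM = 6  # 4 + 1 + 1

MAX_DEGREE = 10
MAX_IMPLICIT_VALENCE = 6


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be turned into a molecular graph."""


@dataclass(frozen=True)
class DrugRecord:
    id: str
    smiles: str


@dataclass(frozen=True)
class DDITuple:
    drug_x: str
    drug_y: str
    relation: int
    label: int = 1


@dataclass
class MolecularGraph:
    """Directed-bond molecular graph of one drug.

    ``bond_src[k]``/``bond_dst[k]`` give the endpoints of directed bond k
    (message direction src -> dst); ``reverse_index[k]`` is the opposite
    direction of the same chemical bond.
    """

    atom_features: np.ndarray  # (n_atoms, 42)
    bond_features: np.ndarray  # (n_directed_bonds, 6)
    bond_src: np.ndarray  # (n_directed_bonds,) int
    bond_dst: np.ndarray  # (n_directed_bonds,) int
    reverse_index: np.ndarray  # (n_directed_bonds,) int
    smiles: str = ""
    motif_atoms: dict = field(default_factory=dict)  # optional annotations

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]

    @property
    def n_directed_bonds(self) -> int:
        return self.bond_features.shape[0]

    def neighbors(self, i: int) -> np.ndarray:
        """Atom indices bonded to atom ``i``."""
        return self.bond_dst[self.bond_src == i]

    def to_json(self) -> str:
        return json.dumps(
            {
                "smiles": self.smiles,
                "atom_features": self.atom_features.tolist(),
                "bond_features": self.bond_features.tolist(),
                "bond_src": self.bond_src.tolist(),
                "bond_dst": self.bond_dst.tolist(),
                "reverse_index": self.reverse_index.tolist(),
            }
        )


def featurize_atom(atom: Chem.Atom) -> np.ndarray:
    """42-dimensional feature vector of one RDKit atom."""
    v = np.zeros(ATOM_FDIM)
    sym = atom.GetSymbol()
    v[ELEMENTS.index(sym) if sym in ELEMENTS else 15] = 1.0

    degree = atom.GetDegree()  # heavy-atom neighbors (H implicit)
    if degree > MAX_DEGREE:
        log.warning("degree %d clamped to %d", degree, MAX_DEGREE)
        degree = MAX_DEGREE
    v[16 + degree] = 1.0

    hyb = atom.GetHybridization()
    if hyb in HYBRIDIZATIONS:
        v[27 + HYBRIDIZATIONS.index(hyb)] = 1.0
    else:
        log.warning("hybridization %s outside listed states; all-zero block", hyb)

    valence = atom.GetImplicitValence()
    if valence > MAX_IMPLICIT_VALENCE:
        log.warning("implicit valence %d clamped to %d", valence, MAX_IMPLICIT_VALENCE)
        valence = MAX_IMPLICIT_VALENCE
    v[32 + valence] = 1.0

    v[39] = atom.GetNumRadicalElectrons()
    v[40] = atom.GetFormalCharge()
    v[41] = 1.0 if atom.GetIsAromatic() else 0.0
    return v


def featurize_bond(bond: Chem.Bond) -> np.ndarray:
    """6-dimensional feature vector of one RDKit bond."""
    v = np.zeros(BOND_FDIM)
    bt = bond.GetBondType()
    if bt in BOND_TYPES:
        v[BOND_TYPES.index(bt)] = 1.0
    else:
        log.warning("bond type %s outside listed types; all-zero block", bt)
    v[4] = 1.0 if bond.GetIsConjugated() else 0.0
    v[5] = 1.0 if bond.IsInRing() else 0.0
    return v


def canonical_mol(smiles: str) -> Chem.Mol:
    """RDKit molecule in canonical atom order, largest fragment only.

    All graph-level atom indices in this package (feature rows, importance
    weights, motif annotations) refer to this ordering.
    """
    if not smiles or not smiles.strip():
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"invalid SMILES: {smiles!r}")
    frags = rdmolops.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        mol = max(frags, key=lambda m: m.GetNumAtoms())
    if mol.GetNumAtoms() == 0:
        raise SmilesParseError(f"no heavy atoms in {smiles!r}")
    # canonical atom ranking makes the ordering deterministic across
    # equivalent SMILES spellings
    order = tuple(int(i) for i in Chem.CanonicalRankAtoms(mol, breakTies=True))
    return Chem.RenumberAtoms(mol, [int(i) for i in np.argsort(order)])


def parse_smiles(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into an attributed directed-bond graph.

    The largest covalent fragment is kept (salt stripping); atom order is
    RDKit's canonical order, so the same SMILES always yields byte-identical
    feature arrays.

    Raises
    ------
    SmilesParseError
        If the string is not valid SMILES or has no heavy atoms.
    """
    mol = canonical_mol(smiles)
    atom_features = np.array([featurize_atom(a) for a in mol.GetAtoms()]).reshape(
        mol.GetNumAtoms(), ATOM_FDIM
    )
    src, dst, bfeats = [], [], []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        f = featurize_bond(bond)
        src += [i, j]
        dst += [j, i]
        bfeats += [f, f]
    n_bonds = len(src)
    reverse = np.arange(n_bonds) ^ 1  # consecutive pairs are reverses
    return MolecularGraph(
        atom_features=atom_features,
        bond_features=np.array(bfeats).reshape(n_bonds, BOND_FDIM),
        bond_src=np.array(src, dtype=np.intp),
        bond_dst=np.array(dst, dtype=np.intp),
        reverse_index=reverse,
        smiles=smiles,
    )


def permute_graph(graph: MolecularGraph, perm: np.ndarray) -> MolecularGraph:
    """Relabel atoms: new atom ``perm[i]`` is old atom ``i``.

    Used for permutation-equivariance checks; bond order is preserved.
    """
    perm = np.asarray(perm, dtype=np.intp)
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    return MolecularGraph(
        atom_features=graph.atom_features[inv],
        bond_features=graph.bond_features.copy(),
        bond_src=perm[graph.bond_src],
        bond_dst=perm[graph.bond_dst],
        reverse_index=graph.reverse_index.copy(),
        smiles=graph.smiles,
    )


# -- tabular I/O ----------------------------------------------------------


class TableFormatError(ValueError):
    """Raised on malformed drug or DDI tables."""


def _read_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return pd.read_csv(path, sep=sep, dtype=str)


def read_drug_table(path) -> list[DrugRecord]:
    """Read a CSV/TSV with columns ``id,smiles`` into drug records."""
    df = _read_table(path)
    missing = {"id", "smiles"} - set(df.columns)
    if missing:
        raise TableFormatError(f"drug table {path} missing columns: {sorted(missing)}")
    dup = df["id"][df["id"].duplicated()].tolist()
    if dup:
        raise TableFormatError(f"duplicate drug ids: {sorted(set(dup))}")
    return [DrugRecord(id=r.id, smiles=r.smiles) for r in df.itertuples(index=False)]


def read_ddi_table(path, drugs: list[DrugRecord]) -> tuple[list[DDITuple], dict[int, int]]:
    """Read a CSV/TSV of ``drug_x,drug_y,type`` rows.

    Relation ids are densified to 0..K-1 (sorted by original id); the
    mapping ``original -> dense`` is returned alongside the tuples.  An
    optional ``label`` column is honored (default 1).
    """
    df = _read_table(path)
    missing = {"drug_x", "drug_y", "type"} - set(df.columns)
    if missing:
        raise TableFormatError(f"DDI table {path} missing columns: {sorted(missing)}")
    known = {d.id for d in drugs}
    for row_no, r in enumerate(df.itertuples(index=False), start=2):
        for col in (r.drug_x, r.drug_y):
            if col not in known:
                raise TableFormatError(f"row {row_no}: unknown drug id {col!r}")
    raw = df["type"].astype(int)
    relabel = {int(orig): dense for dense, orig in enumerate(sorted(raw.unique()))}
    labels = df["label"].astype(int) if "label" in df.columns else pd.Series(1, index=df.index)
    tuples = [
        DDITuple(drug_x=x, drug_y=y, relation=relabel[t], label=int(lab))
        for x, y, t, lab in zip(df["drug_x"], df["drug_y"], raw, labels)
    ]
    return tuples, relabel


def write_drug_table(path, drugs: list[DrugRecord]) -> None:
    pd.DataFrame({"id": [d.id for d in drugs], "smiles": [d.smiles for d in drugs]}).to_csv(
        path, index=False
    )


def write_ddi_table(path, tuples: list[DDITuple]) -> None:
    pd.DataFrame(
        {
            "drug_x": [t.drug_x for t in tuples],
            "drug_y": [t.drug_y for t in tuples],
            "type": [t.relation for t in tuples],
            "label": [t.label for t in tuples],
        }
    ).to_csv(path, index=False)
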