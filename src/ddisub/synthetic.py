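"""Self-contained synthetic drug/DDI datasets with planted structure.

Real DDI corpora associate interaction types with the presence of specific
functional groups in the two partners.  The generator emulates exactly that
causal structure at toy scale: small molecules are assembled from a
fragment library, and typed interactions are planted by *motif rules* — a
pair of SMARTS patterns plus a relation id.  A tuple (d_x, d_y, r) is a
positive precisely when d_x contains the rule's first motif and d_y the
second (labels are then flipped with a small noise rate).  Because the
matched motif atoms are recorded per tuple, a trained model's attention can
be checked against the planted ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

from .molgraph import DDITuple, DrugRecord, canonical_mol

RDLogger.DisableLog("rdApp.*")  # assembly retries would otherwise spam stderr

__all__ = ["MotifRule", "SyntheticDataset", "FRAGMENT_LIBRARY", "DEFAULT_RULES",
           "generate_drugs", "generate_ddi_dataset", "generate_dataset",
           "motif_atoms"]

# ~30 small valid fragments: alkyl chains, rings, amide, carboxyl, amine,
# ester, halides, and a few common heterocycles / polar groups.  Weights
# skew sampling toward functional-group carriers so the default motif rules
# find partners in a substantial share of generated drugs.
FRAGMENT_LIBRARY: tuple[str, ...] = (
    "C", "CC", "CCC", "CCCC", "C(C)C", "CCO", "CO",
    "c1ccccc1", "c1ccncc1", "c1ccc2ccccc2c1", "C1CCCCC1", "C1CCNCC1",
    "CC(N)=O", "CNC(C)=O", "NC=O",
    "CC(=O)O", "OC(=O)CC",
    "CN", "N", "CCN", "NCC",
    "COC(C)=O", "CCOC(C)=O",
    "CCl", "CBr", "CF", "ClCCCl", "FC(F)F",
    "CS", "CC#N", "C=C", "C#C", "O",
)

FRAGMENT_WEIGHTS: tuple[float, ...] = (
    1, 1, 1, 1, 1, 1, 1,
    4, 1, 2, 1, 1,
    1, 1, 1,
    3, 3,
    1.5, 1.5, 1.5, 1.5,
    1, 1,
    1.5, 1.5, 1.5, 1, 1,
    1, 1, 1, 1, 1,
)


@dataclass(frozen=True)
class MotifRule:
    """A planted interaction rule: motif in d_x + motif in d_y -> type r."""

    motif_x: str  # SMARTS
    motif_y: str  # SMARTS
    relation: int
    noise_rate: float = 0.0

    def __post_init__(self):
        for pat in (self.motif_x, self.motif_y):
            if Chem.MolFromSmarts(pat) is None:
                raise ValueError(f"invalid SMARTS: {pat!r}")
        if not 0.0 <= self.noise_rate < 0.5:
            raise ValueError("noise_rate must be in [0, 0.5)")


DEFAULT_RULES: tuple[MotifRule, ...] = (
    # carboxylic acid meets free amine
    MotifRule("[CX3](=O)[OX2H1]", "[NX3;H2,H1;!$(NC=O)]", relation=0),
    # halogen meets aromatic ring
    MotifRule("[F,Cl,Br,I]", "c1ccccc1", relation=1),
)


@dataclass
class SyntheticDataset:
    drugs: list[DrugRecord]
    tuples: list[DDITuple]
    provenance: dict = field(default_factory=dict)

    def save(self, drug_path, ddi_path, provenance_path=None) -> None:
        from .molgraph import write_ddi_table, write_drug_table

        write_drug_table(drug_path, self.drugs)
        write_ddi_table(ddi_path, self.tuples)
        if provenance_path is not None:
            with open(provenance_path, "w") as fh:
                json.dump(self.provenance, fh, indent=1)


def motif_atoms(smiles: str, smarts: str) -> list[int]:
    """Atom indices (canonical graph order) matched by a SMARTS pattern."""
    mol = canonical_mol(smiles)
    pat = Chem.MolFromSmarts(smarts)
    hits: set[int] = set()
    for match in mol.GetSubstructMatches(pat):
        hits.update(match)
    return sorted(hits)


def _assemble(rng: np.random.Generator, fragments: tuple[str, ...],
              n_frags: int, weights: np.ndarray, max_tries: int = 50) -> str | None:
    """Join fragments by single bonds at atoms with spare valence."""
    for _ in range(max_tries):
        picks = [fragments[i] for i in rng.choice(len(fragments), size=n_frags, p=weights)]
        mol = Chem.MolFromSmiles(picks[0])
        ok = mol is not None
        for frag_smiles in picks[1:]:
            if not ok:
                break
            frag = Chem.MolFromSmiles(frag_smiles)
            combo = Chem.RWMol(Chem.CombineMols(mol, frag))
            left = [a.GetIdx() for a in combo.GetAtoms()
                    if a.GetIdx() < mol.GetNumAtoms() and a.GetNumImplicitHs() >= 1]
            right = [a.GetIdx() for a in combo.GetAtoms()
                     if a.GetIdx() >= mol.GetNumAtoms() and a.GetNumImplicitHs() >= 1]
            if not left or not right:
                ok = False
                break
            combo.AddBond(int(left[rng.integers(len(left))]),
                          int(right[rng.integers(len(right))]),
                          Chem.BondType.SINGLE)
            try:
                mol = combo.GetMol()
                Chem.SanitizeMol(mol)
            except Exception:
                ok = False
        if ok:
            return Chem.MolToSmiles(mol)
    return None


def generate_drugs(n: int, seed: int = 0,
                   fragments: tuple[str, ...] = FRAGMENT_LIBRARY,
                   weights: tuple[float, ...] | None = None) -> list[DrugRecord]:
    """``n`` unique small molecules built from 1-3 library fragments."""
    if n < 2:
        raise ValueError("need n >= 2 drugs")
    if weights is None:
        weights = FRAGMENT_WEIGHTS if fragments is FRAGMENT_LIBRARY else (1.0,) * len(fragments)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    drugs: list[DrugRecord] = []
    tries = 0
    while len(drugs) < n:
        tries += 1
        if tries > 200 * n:
            raise RuntimeError("fragment assembly failed to produce enough unique drugs")
        smiles = _assemble(rng, fragments, int(rng.integers(1, 4)), w)
        if smiles is None or smiles in seen:
            continue
        seen.add(smiles)
        drugs.append(DrugRecord(id=f"D{len(drugs):04d}", smiles=smiles))
    return drugs


def random_tuples(drugs: list[DrugRecord], n: int, n_relations: int = 2,
                  seed: int = 0) -> list[DDITuple]:
    """``n`` distinct random positive tuples (no planted structure).

    Used for capacity/memorization experiments where learnability from
    structure is not the point.
    """
    rng = np.random.default_rng(seed)
    pairs = [(a.id, b.id) for a in drugs for b in drugs if a.id != b.id]
    if n > len(pairs):
        raise ValueError(f"cannot draw {n} distinct pairs from {len(pairs)}")
    idx = rng.choice(len(pairs), size=n, replace=False)
    return [DDITuple(pairs[i][0], pairs[i][1],
                     int(rng.integers(n_relations)), label=1) for i in idx]


def _eligible_pairs(drugs: list[DrugRecord], rule: MotifRule) -> list[tuple[str, str]]:
    has_x = [d.id for d in drugs if motif_atoms(d.smiles, rule.motif_x)]
    has_y = [d.id for d in drugs if motif_atoms(d.smiles, rule.motif_y)]
    return [(x, y) for x in has_x for y in has_y if x != y]


def positive_closure(drugs: list[DrugRecord],
                     rules: tuple[MotifRule, ...] = DEFAULT_RULES
                     ) -> set[tuple[str, str, int]]:
    """All (drug_x, drug_y, relation) keys the rules declare to interact.

    This is the complete ground-truth interaction set of the synthetic
    world — a superset of any sampled dataset — used for filtered negative
    sampling, so a corruption never lands on an unsampled true interaction.
    """
    keys: set[tuple[str, str, int]] = set()
    for rule in rules:
        for x, y in _eligible_pairs(drugs, rule):
            keys.add((x, y, rule.relation))
    return keys


def generate_ddi_dataset(drugs: list[DrugRecord],
                         rules: tuple[MotifRule, ...] = DEFAULT_RULES,
                         n_tuples: int = 100, seed: int = 0) -> SyntheticDataset:
    """Sample positive tuples satisfying the planted motif rules.

    Each drug pair occurs at most once across the whole dataset (one type
    per pair).  Labels of sampled positives are flipped with the rule's
    noise rate.  The provenance records, per tuple, the rule and the motif
    atom indices in each drug — the ground truth for explanation-recovery
    experiments.
    """
    if not rules:
        raise ValueError("need at least one rule")
    rng = np.random.default_rng(seed)
    smiles_of = {d.id: d.smiles for d in drugs}
    pools = []
    for rule in rules:
        pairs = _eligible_pairs(drugs, rule)
        rng.shuffle(pairs)
        pools.append(pairs)
    if n_tuples > 0 and all(not p for p in pools):
        raise ValueError("no drug pair satisfies any rule")

    tuples: list[DDITuple] = []
    records: list[dict] = []
    used: set[tuple[str, str]] = set()
    cursors = [0] * len(rules)
    allocation = {rule.relation: 0 for rule in rules}
    while len(tuples) < n_tuples:
        progressed = False
        for ri, (rule, pool) in enumerate(zip(rules, pools)):
            if len(tuples) >= n_tuples:
                break
            while cursors[ri] < len(pool):
                x, y = pool[cursors[ri]]
                cursors[ri] += 1
                if (x, y) in used or (y, x) in used:
                    continue
                used.add((x, y))
                label = 1
                if rule.noise_rate > 0 and rng.random() < rule.noise_rate:
                    label = 0
                tuples.append(DDITuple(x, y, rule.relation, label=label))
                allocation[rule.relation] += 1
                records.append({
                    "drug_x": x, "drug_y": y, "relation": rule.relation,
                    "label": label,
                    "motif_atoms_x": motif_atoms(smiles_of[x], rule.motif_x),
                    "motif_atoms_y": motif_atoms(smiles_of[y], rule.motif_y),
                })
                progressed = True
                break
        if not progressed:
            break  # pools exhausted
    provenance = {
        "seed": seed,
        "n_requested": n_tuples,
        "rules": [{"motif_x": r.motif_x, "motif_y": r.motif_y,
                   "relation": r.relation, "noise_rate": r.noise_rate}
                  for r in rules],
        "allocation": allocation,
        "tuples": records,
    }
    return SyntheticDataset(drugs=list(drugs), tuples=tuples, provenance=provenance)


def generate_dataset(n_drugs: int, n_tuples: int, seed: int = 0,
                     rules: tuple[MotifRule, ...] = DEFAULT_RULES,
                     noise_rate: float | None = None,
                     min_coverage: float = 0.1,
                     max_resamples: int = 20) -> SyntheticDataset:
    """Drugs + tuples in one call, resampling drugs until every motif is
    present in at least ``min_coverage`` of them."""
    if noise_rate is not None:
        rules = tuple(
            MotifRule(r.motif_x, r.motif_y, r.relation, noise_rate) for r in rules
        )
    for attempt in range(max_resamples):
        drugs = generate_drugs(n_drugs, seed=seed + 7919 * attempt)
        coverage_ok = all(
            sum(1 for d in drugs if motif_atoms(d.smiles, pat)) >= min_coverage * n_drugs
            for rule in rules for pat in (rule.motif_x, rule.motif_y)
        )
        if coverage_ok:
            return generate_ddi_dataset(drugs, rules, n_tuples, seed=seed)
    raise RuntimeError(
        f"motif coverage below {min_coverage:.0%} after {max_resamples} drug resamples"
    )
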