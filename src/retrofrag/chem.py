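"""Molecules, atom-mapped reactions and reaction-center extraction.

Reactions are USPTO-style SMILES — ``reactants>>product`` with ``:n`` atom-map
labels establishing atom correspondence across the arrow.  The bonds formed or
broken in a reaction (its reaction center) are identified purely from those
maps: a bond is keyed by the unordered pair of map numbers of its endpoints,
and a key present on one side but not the other (or present with a different
bond order) marks a change.  Bond-order changes are recorded as a broken bond
plus a formed bond, since the map pair is the only identity the format
guarantees across sides.

Only heavy-atom bonds are considered; implicit-hydrogen count changes are not
treated as bond changes.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

ELEMENTS = ["C", "N", "O", "S", "F", "Cl", "Br", "I", "P"]  # + "other" slot
MAX_DEGREE = 5
# feature layout: [mask, element one-hot (10), degree one-hot (6), charge,
#                  aromatic, in-ring]
N_ATOM_FEATURES = 1 + len(ELEMENTS) + 1 + (MAX_DEGREE + 1) + 3

_EN = {"H": 2.20, "C": 2.55, "N": 3.04, "O": 3.44, "S": 2.58, "F": 3.98,
       "Cl": 3.16, "Br": 2.96, "I": 2.66, "P": 2.19, "B": 2.04, "Si": 1.90}


class RetrofragError(Exception):
    """Base class for package errors."""


class MoleculeParseError(RetrofragError):
    pass


class ReactionFormatError(RetrofragError):
    pass


class MappingError(RetrofragError):
    pass


def electronegativity(symbol: str) -> float:
    return _EN.get(symbol, 2.2)


def _atom_feature_row(atom: Chem.Atom) -> np.ndarray:
    row = np.zeros(N_ATOM_FEATURES)
    sym = atom.GetSymbol()
    try:
        k = ELEMENTS.index(sym)
    except ValueError:
        k = len(ELEMENTS)
    row[1 + k] = 1.0
    deg = min(atom.GetDegree(), MAX_DEGREE)
    row[1 + len(ELEMENTS) + 1 + deg] = 1.0
    base = 1 + len(ELEMENTS) + 1 + MAX_DEGREE + 1
    row[base] = float(atom.GetFormalCharge())
    row[base + 1] = float(atom.GetIsAromatic())
    row[base + 2] = float(atom.IsInRing())
    return row


@dataclass(frozen=True)
class AtomInfo:
    element: str
    formal_charge: int
    aromatic: bool


@dataclass
class MolecularGraph:
    """Attribute-annotated molecular graph.

    ``bonds`` store unordered pairs with ``i < j``; ``order`` uses RDKit's
    double coding (1.0, 1.5 aromatic, 2.0, 3.0).  Augmented views produced for
    the contrastive encoder may have no underlying RDKit molecule
    (``mol is None``) — they are encoder inputs, not claimed chemical
    structures.
    """

    atoms: list  # list[AtomInfo]
    bonds: list  # list[tuple[int, int, float]]
    atom_features: np.ndarray  # (n_atoms, N_ATOM_FEATURES)
    canonical_smiles: str | None = None
    mol: object | None = None
    atom_maps: list = field(default_factory=list)  # 0 = unmapped

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    @classmethod
    def from_mol(cls, mol: Chem.Mol) -> "MolecularGraph":
        atoms = [AtomInfo(a.GetSymbol(), a.GetFormalCharge(), a.GetIsAromatic())
                 for a in mol.GetAtoms()]
        bonds = []
        for b in mol.GetBonds():
            i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            if i > j:
                i, j = j, i
            bonds.append((i, j, b.GetBondTypeAsDouble()))
        bonds.sort()
        feats = (np.vstack([_atom_feature_row(a) for a in mol.GetAtoms()])
                 if mol.GetNumAtoms() else np.zeros((0, N_ATOM_FEATURES)))
        maps = [a.GetAtomMapNum() for a in mol.GetAtoms()]
        stripped = Chem.Mol(mol)
        for a in stripped.GetAtoms():
            a.SetAtomMapNum(0)
        return cls(atoms=atoms, bonds=bonds, atom_features=feats,
                   canonical_smiles=Chem.MolToSmiles(stripped), mol=mol,
                   atom_maps=maps)

    def bond_index(self, i: int, j: int) -> int:
        if i > j:
            i, j = j, i
        for k, (a, b, _) in enumerate(self.bonds):
            if (a, b) == (i, j):
                return k
        raise IndexError(f"no bond between atoms {i} and {j}")

    def neighbors(self, i: int):
        out = []
        for a, b, _ in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return out


def parse_molecule(smiles: str) -> MolecularGraph:
    """Parse and sanitize a SMILES string; atom-map numbers are retained."""
    if not smiles or not smiles.strip():
        raise MoleculeParseError("empty SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeParseError(f"cannot parse SMILES: {smiles!r}")
    return MolecularGraph.from_mol(mol)


@dataclass
class Reaction:
    reactants: list  # list[MolecularGraph]
    product: MolecularGraph
    map_complete: bool
    smiles: str = ""


@dataclass(frozen=True)
class BondChange:
    kind: str  # "formed" | "broken"
    map_pair: frozenset  # two atom-map numbers
    order: float  # bond order on the side where the bond exists

    def __post_init__(self):
        assert self.kind in ("formed", "broken")


@dataclass
class BondLabelRecord:
    graph: MolecularGraph
    bond_index: int
    label: str  # "altered" | "unaltered"
    reaction_index: int = -1


def _check_unique_maps(graphs, side: str):
    seen = set()
    for g in graphs:
        for m in g.atom_maps:
            if m > 0:
                if m in seen:
                    raise MappingError(
                        f"duplicate atom-map number {m} on {side} side")
                seen.add(m)
    return seen


def parse_reaction(rxn_smiles: str) -> Reaction:
    """Parse a ``reactants>>product`` SMILES into a :class:`Reaction`.

    ``map_complete`` is true when every product atom is mapped, maps are
    unique within each side, and every product map occurs among the reactants.
    Unmapped reactants (spectators/reagents) are retained.
    """
    if ">>" not in rxn_smiles:
        raise ReactionFormatError("reaction SMILES must contain '>>'")
    left, right = rxn_smiles.split(">>", 1)
    if not left.strip() or not right.strip():
        raise ReactionFormatError("empty reactant or product side")
    reactants = [parse_molecule(part) for part in left.split(".")]
    product = parse_molecule(right)
    r_maps = _check_unique_maps(reactants, "reactant")
    p_maps = _check_unique_maps([product], "product")
    map_complete = (all(m > 0 for m in product.atom_maps)
                    and p_maps <= r_maps and len(p_maps) > 0)
    return Reaction(reactants=reactants, product=product,
                    map_complete=map_complete, smiles=rxn_smiles)


def _mapped_bond_table(graph: MolecularGraph) -> dict:
    """{frozenset(map_i, map_j): order} over bonds whose endpoints are mapped."""
    table = {}
    for i, j, order in graph.bonds:
        mi, mj = graph.atom_maps[i], graph.atom_maps[j]
        if mi > 0 and mj > 0:
            table[frozenset((mi, mj))] = order
    return table


def changed_bonds(reaction: Reaction) -> set:
    """Reaction center: the set of :class:`BondChange` derived from atom maps."""
    if not reaction.map_complete:
        raise MappingError("changed_bonds requires a map-complete reaction")
    r_table = {}
    for g in reaction.reactants:
        r_table.update(_mapped_bond_table(g))
    p_table = _mapped_bond_table(reaction.product)
    changes = set()
    for pair, order in p_table.items():
        if pair not in r_table:
            changes.add(BondChange("formed", pair, order))
        elif r_table[pair] != order:
            changes.add(BondChange("broken", pair, r_table[pair]))
            changes.add(BondChange("formed", pair, order))
    for pair, order in r_table.items():
        if pair not in p_table:
            changes.add(BondChange("broken", pair, order))
    return changes


def _locate(graph: MolecularGraph, pair: frozenset) -> int | None:
    idx = {m: k for k, m in enumerate(graph.atom_maps) if m > 0}
    a, b = tuple(pair)
    if a in idx and b in idx:
        try:
            return graph.bond_index(idx[a], idx[b])
        except IndexError:
            return None
    return None


def build_bond_dataset(reactions, negatives_per_positive: int = 1,
                       seed: int = 0) -> list:
    """Altered/unaltered bond records for breakage classification.

    One ``altered`` record per changed bond (formed bonds located in the
    product, broken bonds in the reactant that carries both mapped atoms), and
    ``negatives_per_positive`` seeded uniformly-sampled ``unaltered`` bonds per
    altered bond from the same graph, without replacement.  Sampling is seeded
    per reaction so the result does not depend on list order.
    """
    if negatives_per_positive < 1:
        raise ValueError("negatives_per_positive must be >= 1")
    records = []
    for r_idx, reaction in enumerate(reactions):
        changes = changed_bonds(reaction)
        per_graph = {}  # id(graph) -> (graph, [altered bond indices])
        for ch in changes:
            if ch.kind == "formed":
                candidates = [reaction.product]
            else:
                candidates = reaction.reactants + [reaction.product]
            for g in candidates:
                k = _locate(g, ch.map_pair)
                if k is not None:
                    per_graph.setdefault(id(g), (g, []))[1].append(k)
                    break
        rng = np.random.default_rng(seed + 9973 * r_idx)
        for g, altered in per_graph.values():
            altered = sorted(set(altered))
            for k in altered:
                records.append(BondLabelRecord(g, k, "altered", r_idx))
            pool = [k for k in range(g.n_bonds) if k not in set(altered)]
            want = negatives_per_positive * len(altered)
            if not pool:
                logger.warning(
                    "reaction %d: graph %s has no unaltered bonds; "
                    "negative records skipped", r_idx, g.canonical_smiles)
                continue
            if len(pool) < want:
                logger.warning(
                    "reaction %d: only %d unaltered bonds for %d requested",
                    r_idx, len(pool), want)
                want = len(pool)
            chosen = rng.choice(len(pool), size=want, replace=False)
            for c in sorted(chosen):
                records.append(BondLabelRecord(g, pool[c], "unaltered", r_idx))
    return records


# ---------------------------------------------------------------------------
# file interfaces
# ---------------------------------------------------------------------------


def read_reactions(path) -> list:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(parse_reaction(line.split()[0]))
    return out


def read_molecules(path) -> list:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(parse_molecule(line.split()[0]))
    return out


def canonical_atom_order(mol: Chem.Mol) -> list:
    """Position of each input atom in RDKit's canonical SMILES output order."""
    stripped = Chem.Mol(mol)
    for a in stripped.GetAtoms():
        a.SetAtomMapNum(0)
    Chem.MolToSmiles(stripped)
    order = list(map(int, stripped.GetProp("_smilesAtomOutputOrder")
                     .strip("[]").split(",")))
    pos = [0] * len(order)
    for canon_pos, input_idx in enumerate(order):
        pos[input_idx] = canon_pos
    return pos


def write_bond_dataset_csv(records, path):
    """CSV with atoms re-indexed into canonical SMILES atom order."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["canonical_smiles", "bond_atom_i", "bond_atom_j", "label"])
        cache = {}
        for rec in records:
            g = rec.graph
            if id(g) not in cache:
                cache[id(g)] = canonical_atom_order(g.mol)
            pos = cache[id(g)]
            i, j, _ = g.bonds[rec.bond_index]
            ci, cj = sorted((pos[i], pos[j]))
            w.writerow([g.canonical_smiles, ci, cj, rec.label])
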