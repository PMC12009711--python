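"""Synthetic fixtures: toy atom-mapped reactions, bond datasets, fragments.

Reactions are built from four condensation/substitution skeletons
(esterification, amide coupling, dehydrative ether formation,
Williamson-style substitution) instantiated with small alkyl/aryl substituent
pools.  Both sides are constructed programmatically with consistent atom-map
numbers, so the formed/broken bonds are known exactly by construction and
serve as ground truth for reaction-center recovery.

The separable bond-classification dataset reuses those reaction centers as
positive bonds; an ``effect_size`` knob mixes in label contamination
(rate 0.5·exp(−effect²)) so that labels are pure noise at effect 0 and nearly
clean at effect 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .chem import BondChange, Reaction, build_bond_dataset, parse_reaction
from .generation import Fragment

FAMILIES = ("esterification", "amide_coupling", "ether_formation",
            "williamson")

DEFAULT_POOL_A = ("C", "CC", "CCC", "C(C)C", "Cc1ccccc1")
DEFAULT_POOL_B = ("C", "CC", "CCC", "c1ccccc1", "CC(C)C")

SPECTATORS = ("CCN(CC)CC", "c1ccncc1")


@dataclass
class ToyReactionSpec:
    families: tuple = FAMILIES
    pool_a: tuple = DEFAULT_POOL_A
    pool_b: tuple = DEFAULT_POOL_B
    n: int = 10
    seed: int = 0
    include_spectators: bool = False

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not self.pool_a or not self.pool_b:
            raise ValueError("substituent pools must be non-empty")
        unknown = set(self.families) - set(FAMILIES)
        if unknown:
            raise ValueError(f"unknown template families: {unknown}")


def _mol(smiles: str) -> Chem.Mol:
    m = Chem.MolFromSmiles(smiles)
    if m is None:
        raise ValueError(f"bad substituent SMILES {smiles!r}")
    return m


def _append_atom(base: Chem.Mol, symbol: str, attach_to: int) -> Chem.Mol:
    em = Chem.RWMol(base)
    idx = em.AddAtom(Chem.Atom(symbol))
    em.AddBond(attach_to, idx, Chem.BondType.SINGLE)
    out = em.GetMol()
    Chem.SanitizeMol(out)
    return out


def _join(first: Chem.Mol, second: Chem.Mol, i: int, j: int) -> Chem.Mol:
    """Combine and bond atom i of `first` to atom j of `second`."""
    em = Chem.RWMol(Chem.CombineMols(first, second))
    em.AddBond(i, first.GetNumAtoms() + j, Chem.BondType.SINGLE)
    out = em.GetMol()
    Chem.SanitizeMol(out)
    return out


def _set_maps(mol: Chem.Mol, start: int) -> Chem.Mol:
    mol = Chem.Mol(mol)
    for k, atom in enumerate(mol.GetAtoms()):
        atom.SetAtomMapNum(start + k)
    return mol


def _condensation(r1: Chem.Mol, r2: Chem.Mol, bond_from: int, bond_to: int,
                  remove: int) -> Chem.Mol:
    """Product: join atom `bond_from` of r1 to atom `bond_to` of the combined
    mol, then delete combined atom `remove` (the leaving group)."""
    em = Chem.RWMol(Chem.CombineMols(r1, r2))
    em.AddBond(bond_from, bond_to, Chem.BondType.SINGLE)
    em.RemoveAtom(remove)
    out = em.GetMol()
    Chem.SanitizeMol(out)
    return out


def _build_family(family: str, sub_a: str, sub_b: str):
    """Returns (r1, r2, product) mols with maps, plus the ground-truth
    (formed_pair, broken_pair) of atom-map numbers."""
    a, b = _mol(sub_a), _mol(sub_b)
    if family == "esterification":
        r1 = _append_atom(a, "O", 0)                  # alcohol, O last
        r2 = _join(_mol("C(=O)O"), b, 0, 0)           # acid: C,O,O then sub
        k = r1.GetNumAtoms()
        r1, r2 = _set_maps(r1, 1), _set_maps(r2, k + 1)
        prod = _condensation(r1, r2, k - 1, k, k + 2)
        formed, broken = (k, k + 1), (k + 1, k + 3)
    elif family == "amide_coupling":
        r1 = _join(_mol("C(=O)O"), a, 0, 0)           # acid first
        r2 = _join(_mol("N"), b, 0, 0)                # amine, N first
        k = r1.GetNumAtoms()
        r1, r2 = _set_maps(r1, 1), _set_maps(r2, k + 1)
        prod = _condensation(r1, r2, 0, k, 2)         # C1-N, drop OH (map 3)
        formed, broken = (1, k + 1), (1, 3)
    elif family == "ether_formation":
        r1 = _append_atom(a, "O", 0)                  # R-OH, O last
        r2 = _join(_mol("O"), b, 0, 0)                # HO-R', O first
        k = r1.GetNumAtoms()
        r1, r2 = _set_maps(r1, 1), _set_maps(r2, k + 1)
        prod = _condensation(r1, r2, k - 1, k + 1, k)  # O(r1)-C, drop O(r2)
        formed, broken = (k, k + 2), (k + 1, k + 2)
    elif family == "williamson":
        r1 = _append_atom(a, "O", 0)
        r2 = _join(_mol("Cl"), b, 0, 0)               # Cl-R', Cl first
        k = r1.GetNumAtoms()
        r1, r2 = _set_maps(r1, 1), _set_maps(r2, k + 1)
        prod = _condensation(r1, r2, k - 1, k + 1, k)  # O-C, drop Cl
        formed, broken = (k, k + 2), (k + 1, k + 2)
    else:
        raise ValueError(f"unknown family {family!r}")
    return r1, r2, prod, formed, broken


def make_toy_reactions(spec: ToyReactionSpec | None = None) -> list:
    """Seeded list of ``(Reaction, {BondChange, ...})`` with exact annotation."""
    spec = spec or ToyReactionSpec()
    rng = np.random.default_rng(spec.seed)
    out = []
    for _ in range(spec.n):
        family = spec.families[int(rng.integers(len(spec.families)))]
        sub_a = spec.pool_a[int(rng.integers(len(spec.pool_a)))]
        sub_b = spec.pool_b[int(rng.integers(len(spec.pool_b)))]
        r1, r2, prod, formed, broken = _build_family(family, sub_a, sub_b)
        parts = [Chem.MolToSmiles(r1, canonical=False),
                 Chem.MolToSmiles(r2, canonical=False)]
        if spec.include_spectators and rng.random() < 0.5:
            parts.append(SPECTATORS[int(rng.integers(len(SPECTATORS)))])
        rxn_smiles = ".".join(parts) + ">>" + Chem.MolToSmiles(
            prod, canonical=False)
        reaction = parse_reaction(rxn_smiles)
        annotation = {BondChange("formed", frozenset(formed), 1.0),
                      BondChange("broken", frozenset(broken), 1.0)}
        out.append((reaction, annotation))
    return out


def make_separable_bond_dataset(n: int, effect_size: float = 2.0,
                                seed: int = 0) -> list:
    """Balanced altered/unaltered bond records with tunable label signal.

    Positives are true reaction-center bonds, negatives non-center bonds of
    the same graphs; each label is independently flipped with probability
    0.5·exp(−effect_size²), so labels carry no information at effect 0 and
    are nearly clean at effect 2.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    if effect_size < 0:
        raise ValueError("effect size must be >= 0")
    rng = np.random.default_rng(seed)
    records = []
    spec_seed = int(rng.integers(2 ** 31))
    n_reactions = max(3, int(np.ceil(n / 3)))
    pairs = make_toy_reactions(ToyReactionSpec(n=n_reactions, seed=spec_seed))
    records = build_bond_dataset([r for r, _ in pairs],
                                 negatives_per_positive=1,
                                 seed=int(rng.integers(2 ** 31)))
    pos = [r for r in records if r.label == "altered"]
    neg = [r for r in records if r.label == "unaltered"]
    half = n // 2
    if len(pos) < half or len(neg) < half:
        raise ValueError("not enough records generated; increase n_reactions")
    keep_pos = [pos[k] for k in rng.choice(len(pos), half, replace=False)]
    keep_neg = [neg[k] for k in rng.choice(len(neg), half, replace=False)]
    dataset = keep_pos + keep_neg
    flip_rate = 0.5 * np.exp(-effect_size ** 2)
    for rec in dataset:
        if rng.random() < flip_rate:
            rec.label = "unaltered" if rec.label == "altered" else "altered"
    order = rng.permutation(len(dataset))
    return [dataset[k] for k in order]


_TOY_FRAGMENTS = (
    ("methyl", "C"),
    ("hydroxyl", "O"),
    ("amino", "N"),
    ("methoxy", "OC", (0,)),
    ("phenyl", "c1ccccc1", (0,)),
    ("acetyl", "CC=O", (1,)),
    ("fluorophenyl", "Fc1ccccc1", (4,)),
)


def make_toy_fragment_library(seed: int = 0) -> list:
    """Curated 7-fragment library; every fragment has >= 1 attachment atom."""
    frags = []
    for entry in _TOY_FRAGMENTS:
        name, smiles = entry[0], entry[1]
        attach = list(entry[2]) if len(entry) > 2 else None
        frags.append(Fragment.from_smiles(smiles, name=name,
                                          attachment_atoms=attach))
    return frags


def write_reactions(pairs, path):
    with open(path, "w") as fh:
        for reaction, _annotation in pairs:
            fh.write(reaction.smiles + "\n")


def write_fragments(frags, path):
    with open(path, "w") as fh:
        for f in frags:
            fh.write(f"{f.smiles} {f.name}\n")
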