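"""Positive-view construction for contrastive learning.

Two families of views of the same molecule:

* graph-level augmentations — node deletion, bond deletion, connected-subgraph
  sampling, attribute masking.  Their outputs are encoder inputs (attributed
  graphs), not claimed chemical structures, and carry no RDKit molecule.
* bond-level views — the retrosynthetic augmentation: bonds a chemist could
  plausibly disconnect (carbon–heteroatom single bonds, amide/ester/ether/
  sulfonamide linkages, acyclic C=C) are located by a SMARTS rule library,
  and each is described by its local chemical environment within a bond-count
  radius.  Two alternative disconnections of one molecule form a positive
  pair: different bonds, same synthetic target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from rdkit import Chem

from .chem import MolecularGraph, electronegativity

logger = logging.getLogger(__name__)

BOND_FEATURE_LENGTH = 10
BOND_FEATURE_NAMES = [
    "aromatic_bonds_in_radius", "nitrogens_in_radius", "oxygens_in_radius",
    "ring_bonds_in_radius", "bond_order", "conjugated", "in_ring",
    "en_difference", "degree_i", "degree_j",
]


class AugmentationError(Exception):
    pass


@dataclass
class AugmentConfig:
    node_drop_fraction: float = 0.15
    bond_delete_fraction: float = 0.15
    mask_fraction: float = 0.15
    subgraph_fraction: float = 0.8
    radius: int = 2
    rules_path: str | None = None  # None -> packaged default library


@dataclass
class BondView:
    graph: MolecularGraph
    bond_index: int
    radius: int
    features: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.features is None:
            self.features = bond_local_features(
                self.graph, self.bond_index, self.radius)


@dataclass
class ViewPair:
    view1: object  # MolecularGraph | BondView
    view2: object
    strategy: str


def _subset_graph(graph: MolecularGraph, keep: list) -> MolecularGraph:
    keep = sorted(keep)
    remap = {old: new for new, old in enumerate(keep)}
    bonds = [(remap[i], remap[j], o) for i, j, o in graph.bonds
             if i in remap and j in remap]
    return MolecularGraph(
        atoms=[graph.atoms[k] for k in keep],
        bonds=bonds,
        atom_features=graph.atom_features[keep].copy(),
        canonical_smiles=None, mol=None,
        atom_maps=[graph.atom_maps[k] for k in keep] if graph.atom_maps else [])


def node_drop(graph: MolecularGraph, fraction: float, seed: int) -> MolecularGraph:
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    n_drop = int(fraction * graph.n_atoms)
    if n_drop == 0:
        return graph
    if n_drop >= graph.n_atoms:
        raise AugmentationError("node_drop would empty the graph")
    rng = np.random.default_rng(seed)
    drop = set(rng.choice(graph.n_atoms, size=n_drop, replace=False).tolist())
    return _subset_graph(graph, [k for k in range(graph.n_atoms) if k not in drop])


def bond_delete(graph: MolecularGraph, fraction: float, seed: int) -> MolecularGraph:
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    # rounded, not floored: a high fraction on a sparse graph (e.g. 0.9 on
    # ethane's single bond) must actually delete something
    n_del = int(np.floor(fraction * graph.n_bonds + 0.5))
    if n_del == 0:
        return graph
    rng = np.random.default_rng(seed)
    drop = set(rng.choice(graph.n_bonds, size=n_del, replace=False).tolist())
    bonds = [b for k, b in enumerate(graph.bonds) if k not in drop]
    return MolecularGraph(atoms=list(graph.atoms), bonds=bonds,
                          atom_features=graph.atom_features.copy(),
                          canonical_smiles=None, mol=None,
                          atom_maps=list(graph.atom_maps))


def subgraph_sample(graph: MolecularGraph, fraction: float, seed: int) -> MolecularGraph:
    """Connected induced subgraph grown by a seeded random walk."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    target = int(np.ceil(fraction * graph.n_atoms))
    if target >= graph.n_atoms:
        return graph
    rng = np.random.default_rng(seed)
    adj = {k: [] for k in range(graph.n_atoms)}
    for i, j, _ in graph.bonds:
        adj[i].append(j)
        adj[j].append(i)
    current = int(rng.integers(graph.n_atoms))
    visited = {current}
    while len(visited) < target:
        frontier = [v for v in adj[current] if v not in visited]
        if not frontier:
            # walk is stuck: restart from any visited atom with an unvisited
            # neighbor; if none exists the component is exhausted
            restart = [v for v in visited
                       if any(u not in visited for u in adj[v])]
            if not restart:
                break
            current = restart[int(rng.integers(len(restart)))]
            continue
        current = frontier[int(rng.integers(len(frontier)))]
        visited.add(current)
    return _subset_graph(graph, sorted(visited))


def attribute_mask(graph: MolecularGraph, fraction: float, seed: int) -> MolecularGraph:
    """Replace selected atoms' attribute rows with the reserved mask token."""
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    n_mask = int(fraction * graph.n_atoms)
    feats = graph.atom_features.copy()
    if n_mask:
        rng = np.random.default_rng(seed)
        rows = rng.choice(graph.n_atoms, size=n_mask, replace=False)
        feats[rows] = 0.0
        feats[rows, 0] = 1.0  # mask flag
    return MolecularGraph(atoms=list(graph.atoms), bonds=list(graph.bonds),
                          atom_features=feats, canonical_smiles=None,
                          mol=None, atom_maps=list(graph.atom_maps))


# ---------------------------------------------------------------------------
# bond-level augmentation
# ---------------------------------------------------------------------------


def load_disconnection_rules(path=None):
    """[(name, SMARTS mol)] from a rule file; bond = pattern atoms :1 and :2."""
    if path is None:
        text = (resources.files("retrofrag") / "data/disconnection_rules.smarts"
                ).read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    rules = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, smarts = line.split(None, 1)
        patt = Chem.MolFromSmarts(smarts.strip())
        if patt is None:
            raise ValueError(f"bad SMARTS in rule {name!r}")
        rules.append((name, patt))
    return rules


_DEFAULT_RULES = None


def candidate_disconnections(graph: MolecularGraph, rules=None) -> list:
    """Bond indices matching the disconnection rule library, deduplicated."""
    global _DEFAULT_RULES
    if graph.mol is None:
        raise ValueError("candidate_disconnections needs a chemical graph")
    if rules is None:
        if _DEFAULT_RULES is None:
            _DEFAULT_RULES = load_disconnection_rules()
        rules = _DEFAULT_RULES
    found = set()
    for _name, patt in rules:
        tagged = {a.GetAtomMapNum(): a.GetIdx() for a in patt.GetAtoms()
                  if a.GetAtomMapNum() in (1, 2)}
        for match in graph.mol.GetSubstructMatches(patt):
            i, j = match[tagged[1]], match[tagged[2]]
            found.add(graph.bond_index(i, j))
    return sorted(found)


def bond_local_features(graph: MolecularGraph, bond_index: int,
                        radius: int) -> np.ndarray:
    """Local-environment descriptor of one bond.

    Counts within `radius` bonds of either endpoint (endpoints and the central
    bond excluded from their own counts): aromatic bonds, nitrogen atoms,
    oxygen atoms, ring bonds; plus central-bond order, conjugation flag, ring
    flag, endpoint electronegativity difference and heavy-atom degrees.
    """
    if not 0 <= bond_index < graph.n_bonds:
        raise IndexError(f"bond index {bond_index} out of range")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    bi, bj, order = graph.bonds[bond_index]

    # BFS distances from the two endpoints jointly
    dist = {bi: 0, bj: 0}
    frontier = [bi, bj]
    d = 0
    while frontier and d < radius:
        d += 1
        nxt = []
        for v in frontier:
            for u in graph.neighbors(v):
                if u not in dist:
                    dist[u] = d
                    nxt.append(u)
        frontier = nxt
    in_hood = set(dist)  # closed neighborhood incl. endpoints

    mol = graph.mol
    n_arom = n_ring_bonds = 0
    for k, (i, j, _o) in enumerate(graph.bonds):
        if k == bond_index or i not in in_hood or j not in in_hood:
            continue
        b = mol.GetBondBetweenAtoms(i, j) if mol is not None else None
        if b is not None:
            n_arom += b.GetIsAromatic()
            n_ring_bonds += b.IsInRing()
        else:
            n_arom += _o == 1.5
    n_nitro = sum(1 for k in in_hood if k not in (bi, bj)
                  and graph.atoms[k].element == "N")
    n_oxy = sum(1 for k in in_hood if k not in (bi, bj)
                and graph.atoms[k].element == "O")

    central = mol.GetBondBetweenAtoms(bi, bj) if mol is not None else None
    conj = float(central.GetIsConjugated()) if central is not None else 0.0
    ring = float(central.IsInRing()) if central is not None else 0.0
    en_diff = abs(electronegativity(graph.atoms[bi].element)
                  - electronegativity(graph.atoms[bj].element))
    deg_i = len(graph.neighbors(bi))
    deg_j = len(graph.neighbors(bj))
    return np.array([n_arom, n_nitro, n_oxy, n_ring_bonds, order, conj, ring,
                     en_diff, float(min(deg_i, deg_j)), float(max(deg_i, deg_j))])


# ---------------------------------------------------------------------------
# positive pairs
# ---------------------------------------------------------------------------

_GRAPH_AUGS = ("node_drop", "bond_delete", "subgraph", "mask")


def _graph_view(graph, config: AugmentConfig, rng) -> MolecularGraph:
    op = _GRAPH_AUGS[int(rng.integers(len(_GRAPH_AUGS)))]
    sub_seed = int(rng.integers(2 ** 31))
    if op == "node_drop":
        try:
            return node_drop(graph, config.node_drop_fraction, sub_seed)
        except AugmentationError:
            return attribute_mask(graph, config.mask_fraction, sub_seed)
    if op == "bond_delete":
        return bond_delete(graph, config.bond_delete_fraction, sub_seed)
    if op == "subgraph":
        return subgraph_sample(graph, config.subgraph_fraction, sub_seed)
    return attribute_mask(graph, config.mask_fraction, sub_seed)


def make_positive_pair(graph: MolecularGraph, strategy: str, seed: int,
                       config: AugmentConfig | None = None) -> ViewPair:
    """Two views of one molecule.

    ``bond_bond`` draws two distinct candidate disconnections (falling back to
    ``graph_graph`` with a logged notice when fewer than two exist);
    ``graph_graph`` applies two independent seeded graph augmentations;
    ``graph_bond`` one of each.
    """
    if strategy not in ("graph_graph", "bond_bond", "graph_bond"):
        raise ValueError(f"unknown strategy {strategy!r}")
    config = config or AugmentConfig()
    rng = np.random.default_rng(seed)
    rules = (load_disconnection_rules(config.rules_path)
             if config.rules_path else None)

    if strategy in ("bond_bond", "graph_bond") and graph.mol is not None:
        candidates = candidate_disconnections(graph, rules)
    else:
        candidates = []

    if strategy == "bond_bond":
        if len(candidates) < 2:
            logger.info("bond_bond: <2 disconnection candidates for %s; "
                        "falling back to graph_graph", graph.canonical_smiles)
            strategy = "graph_graph"
        else:
            pick = rng.choice(len(candidates), size=2, replace=False)
            v1 = BondView(graph, candidates[int(pick[0])], config.radius)
            v2 = BondView(graph, candidates[int(pick[1])], config.radius)
            return ViewPair(v1, v2, "bond_bond")

    if strategy == "graph_bond":
        if not candidates:
            logger.info("graph_bond: no disconnection candidates for %s; "
                        "falling back to graph_graph", graph.canonical_smiles)
            strategy = "graph_graph"
        else:
            v1 = _graph_view(graph, config, rng)
            v2 = BondView(graph, candidates[int(rng.integers(len(candidates)))],
                          config.radius)
            return ViewPair(v1, v2, "graph_bond")

    v1 = _graph_view(graph, config, rng)
    v2 = _graph_view(graph, config, rng)
    return ViewPair(v1, v2, "graph_graph")
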