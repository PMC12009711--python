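"""Graph-level and bond-level augmentations."""

import numpy as np
import pytest

from retrofrag import (bond_local_features, candidate_disconnections,
                       make_positive_pair, node_drop, bond_delete,
                       subgraph_sample, attribute_mask, parse_molecule)
from retrofrag.augment import AugmentationError, BondView, BOND_FEATURE_LENGTH


def graphs_equal(a, b):
    return (a.bonds == b.bonds and a.n_atoms == b.n_atoms
            and np.array_equal(a.atom_features, b.atom_features))


class TestGraphAugmentations:
    def test_node_drop_fraction_zero_identity(self):
        g = parse_molecule("CCO")
        assert node_drop(g, 0.0, 3) is g

    def test_node_drop_benzene_removes_one(self):
        g = parse_molecule("c1ccccc1")
        for seed in range(5):
            assert node_drop(g, 0.2, seed).n_atoms == 5

    def test_node_drop_never_empties(self):
        # floor(fraction * n) < n for fraction < 1, so a single-atom graph
        # survives any legal fraction
        g = parse_molecule("C")
        assert node_drop(g, 0.99, 0).n_atoms == 1
        with pytest.raises(ValueError):
            node_drop(g, 1.0, 0)

    def test_bond_delete_ethane(self):
        g = parse_molecule("CC")
        out = bond_delete(g, 0.9, 0)
        assert out.n_bonds == 0 and out.n_atoms == 2

    def test_subgraph_whole_graph_at_fraction_one(self):
        g = parse_molecule("CCCCC")
        assert subgraph_sample(g, 1.0, 0) is g

    def test_subgraph_pentane_connected_3_path(self):
        # every random-walk outcome on a path graph is a connected 3-path
        g = parse_molecule("CCCCC")
        for seed in range(20):
            out = subgraph_sample(g, 0.6, seed)
            assert out.n_atoms == 3
            assert out.n_bonds == 2  # connected path

    def test_attribute_mask_topology_unchanged(self):
        g = parse_molecule("CCO")
        out = attribute_mask(g, 0.5, 1)
        assert out.bonds == g.bonds and out.n_atoms == g.n_atoms
        assert out.atom_features[:, 0].sum() == 1  # one masked row

    @pytest.mark.parametrize("op,frac", [
        (node_drop, 0.3), (bond_delete, 0.3),
        (subgraph_sample, 0.6), (attribute_mask, 0.3)])
    def test_determinism(self, op, frac):
        g = parse_molecule("CC(=O)Oc1ccccc1C(=O)O")
        assert graphs_equal(op(g, frac, 7), op(g, frac, 7))


class TestCandidateDisconnections:
    def test_ethane_none(self):
        assert candidate_disconnections(parse_molecule("CC")) == []

    def test_benzene_ring_excluded(self):
        assert candidate_disconnections(parse_molecule("c1ccccc1")) == []

    def test_methyl_acetate_both_ester_bonds(self):
        g = parse_molecule("COC(C)=O")
        picked = candidate_disconnections(g)
        co_singles = [k for k, (i, j, o) in enumerate(g.bonds)
                      if o == 1.0 and {g.atoms[i].element,
                                       g.atoms[j].element} == {"C", "O"}]
        assert picked == sorted(co_singles)
        assert len(picked) == 2

    def test_invariant_under_atom_reordering(self):
        for smi1, smi2 in [("CC(=O)OC", "COC(C)=O"),
                           ("NCCO", "OCCN")]:
            def bond_set(smi):
                g = parse_molecule(smi)
                out = set()
                for k in candidate_disconnections(g):
                    i, j, _ = g.bonds[k]
                    from retrofrag.chem import canonical_atom_order
                    pos = canonical_atom_order(g.mol)
                    out.add(frozenset((pos[i], pos[j])))
                return out
            assert bond_set(smi1) == bond_set(smi2)


class TestBondLocalFeatures:
    def test_length_and_ethane(self):
        g = parse_molecule("CC")
        v = bond_local_features(g, 0, 2)
        assert len(v) == BOND_FEATURE_LENGTH
        assert v[0] == 0 and v[1] == 0  # no aromatic bonds, no nitrogens

    def test_pyridine_ring_bond_radius_1(self):
        g = parse_molecule("c1ccncc1")
        # bond between the two atoms adjacent to N on one side
        k = g.bond_index(3, 4)  # N-c bond (atom 3 is N in c1ccncc1)
        v = bond_local_features(g, k, 1)
        assert v[0] >= 2          # aromatic bonds in the 1-neighborhood
        assert v[3] >= 2          # ring bonds likewise
        assert v[4] == 1.5        # central aromatic bond order
        assert v[6] == 1.0        # in ring

    def test_radius_zero_only_central_descriptors(self):
        g = parse_molecule("CCO")
        v = bond_local_features(g, g.bond_index(1, 2), 0)
        assert v[0] == v[1] == v[2] == v[3] == 0
        assert v[4] == 1.0
        assert v[7] == pytest.approx(abs(3.44 - 2.55))  # O vs C

    def test_same_inputs_same_vector(self):
        g = parse_molecule("CC(=O)NC")
        assert np.array_equal(bond_local_features(g, 1, 2),
                              bond_local_features(g, 1, 2))

    def test_out_of_range(self):
        with pytest.raises(IndexError):
            bond_local_features(parse_molecule("CC"), 5, 1)

    def test_automorphism_invariance(self):
        # benzene: all ring bonds are equivalent under automorphism
        g = parse_molecule("c1ccccc1")
        vecs = [bond_local_features(g, k, 2) for k in range(g.n_bonds)]
        for v in vecs[1:]:
            assert np.array_equal(v, vecs[0])


class TestMakePositivePair:
    def test_aspirin_bond_bond(self):
        g = parse_molecule("CC(=O)Oc1ccccc1C(=O)O")
        pair = make_positive_pair(g, "bond_bond", 0)
        assert pair.strategy == "bond_bond"
        assert isinstance(pair.view1, BondView)
        assert isinstance(pair.view2, BondView)
        assert pair.view1.bond_index != pair.view2.bond_index
        cands = set(candidate_disconnections(g))
        assert {pair.view1.bond_index, pair.view2.bond_index} <= cands

    def test_ethane_falls_back_to_graph_graph(self):
        pair = make_positive_pair(parse_molecule("CC"), "bond_bond", 0)
        assert pair.strategy == "graph_graph"

    def test_graph_bond_mix(self):
        g = parse_molecule("CC(=O)OC")
        pair = make_positive_pair(g, "graph_bond", 1)
        assert pair.strategy == "graph_bond"
        assert isinstance(pair.view2, BondView)

    def test_deterministic(self):
        g = parse_molecule("CC(=O)Oc1ccccc1C(=O)O")
        for strategy in ("graph_graph", "bond_bond", "graph_bond"):
            p1 = make_positive_pair(g, strategy, 11)
            p2 = make_positive_pair(g, strategy, 11)
            if isinstance(p1.view1, BondView):
                assert p1.view1.bond_index == p2.view1.bond_index
            else:
                assert graphs_equal(p1.view1, p2.view1)

    def test_unknown_strategy(self):
        with pytest.raises(ValueError):
            make_positive_pair(parse_molecule("CC"), "bogus", 0)
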