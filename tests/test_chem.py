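"""Molecule/reaction parsing and reaction-center extraction."""

import numpy as np
import pytest

from retrofrag import chem
from retrofrag.chem import (MappingError, MoleculeParseError,
                            ReactionFormatError, build_bond_dataset,
                            changed_bonds, parse_molecule, parse_reaction)

ESTER = ("[CH3:1][OH:2].[C:3](=[O:4])([OH:5])[CH3:6]"
         ">>[CH3:1][O:2][C:3](=[O:4])[CH3:6]")
AMIDE = ("[C:1](=[O:2])([OH:3])[CH3:4].[NH2:5][CH3:6]"
         ">>[C:1](=[O:2])([NH:5][CH3:6])[CH3:4]")


def change_pairs(changes):
    return sorted((c.kind, tuple(sorted(c.map_pair))) for c in changes)


class TestParseMolecule:
    def test_benzene(self):
        g = parse_molecule("c1ccccc1")
        assert g.n_atoms == 6 and g.n_bonds == 6
        assert all(o == 1.5 for _, _, o in g.bonds)

    def test_methane(self):
        g = parse_molecule("C")
        assert g.n_atoms == 1 and g.n_bonds == 0

    @pytest.mark.parametrize("bad", ["C(", "", "   ", "C1CC"])
    def test_parse_errors(self, bad):
        with pytest.raises(MoleculeParseError):
            parse_molecule(bad)

    def test_canonical_roundtrip(self):
        g = parse_molecule("OCC")
        g2 = parse_molecule(g.canonical_smiles)
        assert g2.canonical_smiles == g.canonical_smiles
        assert g2.n_atoms == g.n_atoms

    def test_atom_maps_retained(self):
        g = parse_molecule("[CH3:7][OH:2]")
        assert sorted(g.atom_maps) == [2, 7]


class TestParseReaction:
    def test_esterification(self):
        r = parse_reaction(ESTER)
        assert len(r.reactants) == 2
        assert r.map_complete
        assert r.product.n_atoms == 5

    def test_unmapped_flagged(self):
        assert not parse_reaction("CC>>CC").map_complete

    @pytest.mark.parametrize("bad", [">>CC", "CC>>", "CC.CC"])
    def test_format_errors(self, bad):
        with pytest.raises(ReactionFormatError):
            parse_reaction(bad)

    def test_duplicate_map_error(self):
        with pytest.raises(MappingError):
            parse_reaction("[CH3:1][OH:1]>>[CH3:1][OH:2]")

    def test_reactant_order_preserved(self):
        r = parse_reaction(ESTER)
        assert r.reactants[0].n_atoms == 2
        assert r.reactants[1].n_atoms == 4


class TestChangedBonds:
    def test_identity_reaction_empty(self):
        r = parse_reaction("[CH3:1][CH3:2]>>[CH3:1][CH3:2]")
        assert changed_bonds(r) == set()

    def test_esterification(self):
        assert change_pairs(changed_bonds(parse_reaction(ESTER))) == [
            ("broken", (3, 5)), ("formed", (2, 3))]

    def test_amide_coupling(self):
        assert change_pairs(changed_bonds(parse_reaction(AMIDE))) == [
            ("broken", (1, 3)), ("formed", (1, 5))]

    def test_requires_map_complete(self):
        with pytest.raises(MappingError):
            changed_bonds(parse_reaction("CC>>CC"))

    def test_order_change_is_broken_plus_formed(self):
        r = parse_reaction("[CH2:1]=[CH2:2]>>[CH3:1][CH3:2]")
        assert change_pairs(changed_bonds(r)) == [
            ("broken", (1, 2)), ("formed", (1, 2))]

    # mass-balanced reactions (leaving group kept as a product fragment),
    # so the reverse direction is also map-complete
    BALANCED = [
        ESTER.replace(">>", ">>").replace(
            ">>[CH3:1][O:2][C:3](=[O:4])[CH3:6]",
            ">>[CH3:1][O:2][C:3](=[O:4])[CH3:6].[OH2:5]"),
        "[CH2:1]=[CH2:2]>>[CH3:1][CH3:2]",
        "[CH3:1][CH3:2]>>[CH3:1][CH3:2]",
    ]

    @pytest.mark.parametrize("rxn", BALANCED)
    def test_side_swap_exchanges_labels(self, rxn):
        # reversing a balanced reaction exchanges formed and broken exactly
        left, right = rxn.split(">>")
        fwd = {(c.kind, c.map_pair)
               for c in changed_bonds(parse_reaction(rxn))}
        swapped = {("formed" if k == "broken" else "broken", p)
                   for k, p in fwd}
        rev = parse_reaction(right + ">>" + left)
        assert {(c.kind, c.map_pair) for c in changed_bonds(rev)} == swapped


class TestBuildBondDataset:
    def test_counts_and_balance(self):
        recs = build_bond_dataset([parse_reaction(ESTER)], 1, seed=0)
        altered = [r for r in recs if r.label == "altered"]
        unaltered = [r for r in recs if r.label == "unaltered"]
        assert len(altered) >= 1
        assert len(altered) == len(unaltered)

    def test_identity_reaction_yields_nothing(self):
        r = parse_reaction("[CH3:1][CH3:2]>>[CH3:1][CH3:2]")
        assert build_bond_dataset([r], 1, seed=0) == []

    def test_deterministic(self):
        rxns = [parse_reaction(ESTER), parse_reaction(AMIDE)]
        a = build_bond_dataset(rxns, 2, seed=5)
        b = build_bond_dataset(rxns, 2, seed=5)
        assert [(r.label, r.bond_index, r.reaction_index) for r in a] == \
               [(r.label, r.bond_index, r.reaction_index) for r in b]

    def test_altered_records_match_changed_bonds(self):
        r = parse_reaction(ESTER)
        changes = changed_bonds(r)
        recs = build_bond_dataset([r], 1, seed=0)
        altered_pairs = set()
        for rec in recs:
            if rec.label != "altered":
                continue
            i, j, _ = rec.graph.bonds[rec.bond_index]
            altered_pairs.add(frozenset((rec.graph.atom_maps[i],
                                         rec.graph.atom_maps[j])))
        assert altered_pairs == {c.map_pair for c in changes}

    def test_csv_export(self, tmp_path):
        recs = build_bond_dataset([parse_reaction(ESTER)], 1, seed=0)
        path = tmp_path / "bonds.csv"
        chem.write_bond_dataset_csv(recs, path)
        import csv
        with open(path) as fh:
            rows = list(csv.DictReader(fh))
        assert len(rows) == len(recs)
        for row in rows:
            g = parse_molecule(row["canonical_smiles"])
            i, j = int(row["bond_atom_i"]), int(row["bond_atom_j"])
            assert 0 <= i < j < g.n_atoms
            assert row["label"] in ("altered", "unaltered")
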