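"""Fragment MDP mechanics, rewards, policy contracts, route soundness."""

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import QED

from retrofrag import (EncoderConfig, Fragment, HybridEncoder, RLConfig,
                       RewardConfig, STOP, apply_action, composite_reward,
                       generate, init_state, replay_route, train_policy,
                       valid_actions)
from retrofrag.generation import (ActionError, HookError, Policy, StateError,
                                  deterministic_hook_stub, export_routes,
                                  rollout)
from tests.conftest import SMALL


class TestFragment:
    def test_dummy_atom_attachment(self):
        f = Fragment.from_smiles("*CC=O", name="acetyl")
        assert f.mol.GetNumAtoms() == 3
        assert f.attachment_atoms == [0]

    def test_inferred_attachment(self):
        f = Fragment.from_smiles("C")
        assert f.attachment_atoms == [0]

    def test_no_free_valence_rejected(self):
        with pytest.raises(ValueError):
            Fragment.from_smiles("FC(F)(F)F", attachment_atoms=[0])


class TestStatesAndActions:
    def test_benzene_six_sites_empty_route(self):
        st = init_state("c1ccccc1")
        assert len(st.attachment_sites) == 6
        assert st.route == [] and st.step_count == 0

    def test_fully_substituted_only_stop(self, toy_library):
        st = init_state("FC(F)(F)F")  # no free valence anywhere
        acts = valid_actions(st, toy_library)
        assert acts == [STOP]

    def test_bad_scaffold(self):
        from retrofrag.chem import MoleculeParseError
        with pytest.raises(MoleculeParseError):
            init_state("C(")

    def test_benzene_methyl_symmetry_reduction(self, toy_library):
        methyl = [f for f in toy_library if f.name == "methyl"]
        st = init_state("c1ccccc1")
        reduced = valid_actions(st, methyl, symmetry_reduce=True)
        full = valid_actions(st, methyl, symmetry_reduce=False)
        assert len(reduced) == 2   # STOP + one orbit representative
        assert len(full) == 7      # STOP + six equivalent CH sites

    def test_empty_library_only_stop(self):
        assert valid_actions(init_state("c1ccccc1"), []) == [STOP]

    def test_apply_methyl_gives_toluene(self, toy_library):
        methyl = [f for f in toy_library if f.name == "methyl"]
        st = init_state("c1ccccc1")
        act = [a for a in valid_actions(st, methyl) if not a.stop][0]
        new = apply_action(st, act, methyl)
        assert new.smiles == "Cc1ccccc1"
        assert len(new.route) == 1 and new.step_count == 1

    def test_stop_terminates_without_change(self, toy_library):
        st = init_state("c1ccccc1")
        done = apply_action(st, STOP, toy_library)
        assert done.terminated and done.smiles == st.smiles
        with pytest.raises(StateError):
            valid_actions(done, toy_library)

    def test_every_valid_action_sanitizes(self, toy_library):
        st = init_state("Cc1ccccc1O")
        for act in valid_actions(st, toy_library):
            if not act.stop:
                out = apply_action(st, act, toy_library)
                assert Chem.MolFromSmiles(out.smiles) is not None

    def test_unknown_fragment_rejected(self, toy_library):
        from retrofrag.generation import Action
        st = init_state("c1ccccc1")
        with pytest.raises(ActionError):
            apply_action(st, Action(False, "nope", 0, 0), toy_library)


class TestReward:
    def test_all_zero_weights_is_step_penalty(self):
        mol = Chem.MolFromSmiles("c1ccccc1")
        cfg = RewardConfig(w_qed=0, step_penalty=0.1)
        assert composite_reward(mol, cfg, steps=3) == pytest.approx(-0.3)

    def test_qed_only_matches_reference(self):
        mol = Chem.MolFromSmiles("CC(=O)Oc1ccccc1C(=O)O")
        cfg = RewardConfig(w_qed=1.0)
        assert composite_reward(mol, cfg) == pytest.approx(QED.qed(mol))

    def test_monotone_in_weights(self):
        mol = Chem.MolFromSmiles("CCO")
        lo = composite_reward(mol, RewardConfig(w_qed=1.0))
        hi = composite_reward(mol, RewardConfig(w_qed=1.0, w_sa=0.5))
        assert hi >= lo  # SA term is nonnegative

    def test_missing_hook_raises(self):
        mol = Chem.MolFromSmiles("CCO")
        with pytest.raises(HookError):
            composite_reward(mol, RewardConfig(w_external=1.0))

    def test_hook_stub_deterministic(self):
        mol = Chem.MolFromSmiles("CCO")
        cfg = RewardConfig(w_qed=0.0, w_external=1.0,
                           external_hook=deterministic_hook_stub)
        assert composite_reward(mol, cfg) == composite_reward(mol, cfg)


@pytest.fixture(scope="module")
def small_policy(toy_library):
    enc = HybridEncoder(EncoderConfig(**SMALL))
    return Policy(enc, toy_library, RLConfig(seed=0))


class TestPolicyAndGeneration:
    def test_rollout_only_valid_actions(self, small_policy):
        """The masking contract: sampled episodes only visit legal states."""
        rng = np.random.default_rng(0)
        for _ in range(5):
            ep = rollout(small_policy, "c1ccccc1", RewardConfig(), rng)
            assert Chem.MolFromSmiles(ep.final_state.smiles) is not None
            assert ep.final_state.step_count <= RewardConfig().max_steps

    def test_generate_zero(self, small_policy):
        assert generate(small_policy, 0) == []

    def test_generate_deterministic(self, small_policy):
        a = [r.smiles for r in generate(small_policy, 10, seed=4)]
        b = [r.smiles for r in generate(small_policy, 10, seed=4)]
        assert a == b

    def test_generated_all_sanitize_with_routes(self, small_policy,
                                                toy_library):
        results = generate(small_policy, 25, seed=2)
        for res in results:
            assert Chem.MolFromSmiles(res.smiles) is not None
            assert replay_route("c1ccccc1", res.route,
                                toy_library) == res.smiles

    def test_encoder_representation_shapes(self, small_policy):
        st = init_state("c1ccccc1")
        rep = small_policy.encoder.encode_graph(st.graph)
        assert rep.shape == (SMALL["d_h"],)

    def test_train_policy_deterministic_and_logged(self, toy_library):
        kw = dict(episodes=20, batch_episodes=5, seed=3)
        enc = HybridEncoder(EncoderConfig(**SMALL))
        _, h1 = train_policy(toy_library, "c1ccccc1", enc,
                             RewardConfig(), RLConfig(**kw))
        enc2 = HybridEncoder(EncoderConfig(**SMALL))
        _, h2 = train_policy(toy_library, "c1ccccc1", enc2,
                             RewardConfig(), RLConfig(**kw))
        assert h1 == h2
        assert len(h1) == 4

    def test_degenerate_reward_warns(self, toy_library, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="retrofrag.generation"):
            enc = HybridEncoder(EncoderConfig(**SMALL))
            train_policy(toy_library, "c1ccccc1", enc,
                         RewardConfig(w_qed=0.0),
                         RLConfig(episodes=5, batch_episodes=5, seed=0))
        assert any("degenerate" in r.message for r in caplog.records)


class TestRoutes:
    def test_scaffold_only_empty_disconnections(self, small_policy):
        st = init_state("c1ccccc1")
        done = apply_action(st, STOP, small_policy.library)
        from retrofrag.generation import GenerationResult
        docs = export_routes([GenerationResult(done.smiles, done.route, done)])
        assert docs[0]["disconnections"] == []

    def test_toluene_single_disconnection(self, toy_library):
        methyl = [f for f in toy_library if f.name == "methyl"]
        st = init_state("c1ccccc1")
        act = [a for a in valid_actions(st, methyl) if not a.stop][0]
        done = apply_action(apply_action(st, act, methyl), STOP, methyl)
        from retrofrag.generation import GenerationResult
        docs = export_routes([GenerationResult(done.smiles, done.route, done)])
        assert docs[0]["n_steps"] == 1
        (disc,) = docs[0]["disconnections"]
        assert disc["fragment"] == "methyl"
        # the named bond is the exocyclic C-C bond of toluene
        mol = Chem.MolFromSmiles(docs[0]["smiles"])
        bond = mol.GetBondBetweenAtoms(disc["atom_i"], disc["atom_j"])
        assert bond is not None and not bond.GetIsAromatic()

    def test_disconnection_count_equals_route_length(self, small_policy,
                                                     toy_library):
        results = generate(small_policy, 10, seed=8)
        for doc, res in zip(export_routes(results), results):
            assert len(doc["disconnections"]) == len(res.route)
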