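"""Fragment-based reinforced molecule generation with route recording.

Generation is a two-step Markov decision process: starting from a scaffold
(e.g. a benzene ring), each action either STOPs or picks a library fragment
together with one scaffold-side and one fragment-side attachment atom and
forms a single bond between them.  Every candidate action is valence-checked
by actually building and sanitizing the product, so every molecule the policy
can ever emit is chemically valid by construction — the mechanism behind
100% validity.

The policy scores masked actions with a small perceptron over the pretrained
encoder's state representation, the fragment representation and the two
attachment atoms' attribute rows; the encoder is frozen (representation
reuse).  Training is clipped policy gradient against a moving-average reward
baseline.  Each applied action is recorded as a route step; read in reverse,
the route is a retrosynthetic disconnection plan for the final molecule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from . import nn
from .chem import MolecularGraph, canonical_atom_order, parse_molecule
from .encoder import HybridEncoder
from .evaluate import (DEFAULT_CATALOGS, passes_catalog, sa_score)
from rdkit.Chem import QED

logger = logging.getLogger(__name__)


class StateError(Exception):
    pass


class ActionError(Exception):
    pass


class HookError(Exception):
    pass


# ---------------------------------------------------------------------------
# fragments
# ---------------------------------------------------------------------------


@dataclass
class Fragment:
    name: str
    smiles: str
    mol: Chem.Mol
    graph: MolecularGraph
    attachment_atoms: list  # atom indices with free valence

    @classmethod
    def from_smiles(cls, smiles: str, name: str | None = None,
                    attachment_atoms=None) -> "Fragment":
        """Build a fragment; '*' dummy atoms mark attachment points, else
        attachment is inferred as every atom with free valence (>= 1 H)."""
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"cannot parse fragment SMILES {smiles!r}")
        dummies = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
        if dummies:
            attach = set()
            em = Chem.RWMol(mol)
            neighbors = [n.GetIdx() for d in dummies
                         for n in mol.GetAtomWithIdx(d).GetNeighbors()]
            for d in sorted(dummies, reverse=True):
                em.RemoveAtom(d)
            # indices shift after removal; dummies are removed from the end
            shift = sorted(dummies)
            for nb in neighbors:
                attach.add(nb - sum(1 for d in shift if d < nb))
            mol = em.GetMol()
            Chem.SanitizeMol(mol)
            attachment_atoms = sorted(attach)
        elif attachment_atoms is None:
            attachment_atoms = [a.GetIdx() for a in mol.GetAtoms()
                                if a.GetTotalNumHs() >= 1]
        if not attachment_atoms:
            raise ValueError(f"fragment {smiles!r} has no attachment atom")
        for k in attachment_atoms:
            if mol.GetAtomWithIdx(k).GetTotalNumHs() < 1:
                raise ValueError(
                    f"attachment atom {k} of {smiles!r} has no free valence")
        return cls(name=name or Chem.MolToSmiles(mol),
                   smiles=Chem.MolToSmiles(mol), mol=mol,
                   graph=MolecularGraph.from_mol(mol),
                   attachment_atoms=list(attachment_atoms))


def read_fragment_library(path) -> list:
    """One fragment SMILES per line; optional second token is the name."""
    frags = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            frags.append(Fragment.from_smiles(
                parts[0], parts[1] if len(parts) > 1 else None))
    return frags


def brics_fragment_library(molecules, max_fragments: int = 50) -> list:
    """BRICS-style decomposition of seed molecules into a fragment library."""
    from rdkit.Chem import BRICS
    seen, out = set(), []
    for g in molecules:
        if g.mol is None:
            continue
        for smi in BRICS.BRICSDecompose(g.mol):
            clean = smi
            for tag in range(1, 17):
                clean = clean.replace(f"[{tag}*]", "[*]")
            if clean in seen:
                continue
            seen.add(clean)
            try:
                out.append(Fragment.from_smiles(clean))
            except ValueError:
                continue
            if len(out) >= max_fragments:
                return out
    return out


# ---------------------------------------------------------------------------
# states, actions, routes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RouteStep:
    fragment: str
    scaffold_atom: int        # index in the pre-step (= final) numbering
    fragment_atom: int        # index within the fragment
    bond_order: float = 1.0
    n_atoms_before: int = 0   # molecule size before this step


@dataclass(frozen=True)
class Action:
    stop: bool = False
    fragment: str | None = None
    scaffold_atom: int = -1
    fragment_atom: int = -1


STOP = Action(stop=True)


@dataclass
class GenerationState:
    mol: Chem.Mol
    scaffold_smiles: str
    route: list = field(default_factory=list)
    step_count: int = 0
    terminated: bool = False

    @property
    def smiles(self) -> str:
        return Chem.MolToSmiles(self.mol)

    @property
    def attachment_sites(self) -> list:
        return [a.GetIdx() for a in self.mol.GetAtoms()
                if a.GetTotalNumHs() >= 1]

    @property
    def graph(self) -> MolecularGraph:
        return MolecularGraph.from_mol(self.mol)


def init_state(scaffold_smiles: str) -> GenerationState:
    graph = parse_molecule(scaffold_smiles)  # raises on bad input
    return GenerationState(mol=graph.mol, scaffold_smiles=scaffold_smiles)


def _orbit_representatives(mol: Chem.Mol, atoms) -> list:
    """One atom per automorphism orbit among `atoms` (canonical ranks)."""
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=False))
    best = {}
    for a in atoms:
        best.setdefault(ranks[a], a)
    return sorted(best.values())


def _try_attach(mol: Chem.Mol, scaffold_atom: int, fragment: Fragment,
                fragment_atom: int) -> Chem.Mol | None:
    combined = Chem.RWMol(Chem.CombineMols(mol, fragment.mol))
    offset = mol.GetNumAtoms()
    try:
        combined.AddBond(scaffold_atom, offset + fragment_atom,
                         Chem.BondType.SINGLE)
        out = combined.GetMol()
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return out


def valid_actions(state: GenerationState, library,
                  symmetry_reduce: bool = True) -> list:
    """All legal actions (STOP first); every non-STOP action sanitizes."""
    if state.terminated:
        raise StateError("terminated state accepts no actions")
    actions = [STOP]
    sites = state.attachment_sites
    if symmetry_reduce:
        sites = _orbit_representatives(state.mol, sites)
    for frag in library:
        frag_atoms = frag.attachment_atoms
        if symmetry_reduce:
            frag_atoms = _orbit_representatives(
                frag.mol, frag.attachment_atoms)
        for a in sites:
            for b in frag_atoms:
                if _try_attach(state.mol, a, frag, b) is not None:
                    actions.append(Action(False, frag.name, a, b))
    return actions


def apply_action(state: GenerationState, action: Action,
                 library=None) -> GenerationState:
    if state.terminated:
        raise StateError("terminated state accepts no actions")
    if action.stop:
        return GenerationState(mol=state.mol,
                               scaffold_smiles=state.scaffold_smiles,
                               route=list(state.route),
                               step_count=state.step_count, terminated=True)
    frag = _find_fragment(library, action.fragment)
    new_mol = _try_attach(state.mol, action.scaffold_atom, frag,
                          action.fragment_atom)
    if new_mol is None:
        raise ActionError(f"action {action} violates valence")
    step = RouteStep(fragment=frag.name, scaffold_atom=action.scaffold_atom,
                     fragment_atom=action.fragment_atom,
                     n_atoms_before=state.mol.GetNumAtoms())
    return GenerationState(mol=new_mol, scaffold_smiles=state.scaffold_smiles,
                           route=list(state.route) + [step],
                           step_count=state.step_count + 1)


def _find_fragment(library, name) -> Fragment:
    for f in library or ():
        if f.name == name:
            return f
    raise ActionError(f"fragment {name!r} not in library")


# ---------------------------------------------------------------------------
# rewards
# ---------------------------------------------------------------------------


@dataclass
class RewardConfig:
    w_qed: float = 1.0
    w_sa: float = 0.0
    w_filter: float = 0.0
    w_external: float = 0.0
    external_hook: object = None  # callable: smiles -> float
    step_penalty: float = 0.0
    max_steps: int = 8
    catalogs: tuple = DEFAULT_CATALOGS

    def __post_init__(self):
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")


def composite_reward(mol: Chem.Mol, config: RewardConfig,
                     steps: int = 0) -> float:
    """weights · (QED, (10−SA)/9 clipped, filter pass fraction, hook)
    − step_penalty · steps."""
    total = -config.step_penalty * steps
    smiles = Chem.MolToSmiles(mol)
    if config.w_qed:
        total += config.w_qed * float(QED.qed(mol))
    if config.w_sa:
        sa_norm = min(1.0, max(0.0, (10.0 - sa_score(mol)) / 9.0))
        total += config.w_sa * sa_norm
    if config.w_filter:
        frac = np.mean([passes_catalog(smiles, c) for c in config.catalogs])
        total += config.w_filter * float(frac)
    if config.w_external:
        if config.external_hook is None:
            raise HookError(f"external reward weight set but no hook "
                            f"({smiles})")
        try:
            total += config.w_external * float(config.external_hook(smiles))
        except Exception as exc:
            raise HookError(f"external hook failed for {smiles}: {exc}")
    return float(total)


def deterministic_hook_stub(smiles: str) -> float:
    """Deterministic stand-in for an external (e.g. docking) scorer: a
    hash-derived value in [0, 1).  Useful for tests and dry runs."""
    import hashlib
    h = hashlib.sha256(smiles.encode()).digest()
    return int.from_bytes(h[:4], "big") / 2 ** 32


# ---------------------------------------------------------------------------
# policy
# ---------------------------------------------------------------------------


@dataclass
class RLConfig:
    episodes: int = 200
    batch_episodes: int = 10
    learning_rate: float = 3e-3
    clip: float = 0.2
    entropy_coef: float = 0.01
    update_epochs: int = 2
    baseline_momentum: float = 0.9
    hidden: int = 64
    symmetry_reduce: bool = True
    freeze_encoder: bool = True
    seed: int = 0


class Policy:
    """Masked softmax policy over (fragment, scaffold atom, fragment atom)."""

    def __init__(self, encoder: HybridEncoder, library,
                 config: RLConfig | None = None):
        self.encoder = encoder
        self.library = list(library)
        self.config = config or RLConfig()
        d_h = encoder.config.d_h
        from .chem import N_ATOM_FEATURES
        feat_len = 2 * d_h + 2 * N_ATOM_FEATURES
        rng = np.random.default_rng(self.config.seed)
        self.action_mlp = nn.MLP([feat_len, self.config.hidden, 1], rng)
        self.stop_mlp = nn.MLP([d_h, self.config.hidden, 1], rng)
        # zero-init the output layers: the initial policy is uniform over
        # valid actions (STOP included), so early exploration is unbiased
        for mlp in (self.action_mlp, self.stop_mlp):
            mlp.layers[-1].W.data[:] = 0.0
            mlp.layers[-1].b.data[:] = 0.0
        self.frag_reps = {f.name: encoder.encode_graph(f.graph)
                          for f in self.library}

    @property
    def params(self):
        return self.action_mlp.params + self.stop_mlp.params

    def _features(self, state: GenerationState, actions) -> tuple:
        """(stop feature vector, matrix of non-STOP action features)."""
        state_rep = self.encoder.encode_graph(state.graph)
        g = state.graph
        rows = []
        for a in actions:
            if a.stop:
                continue
            frag = _find_fragment(self.library, a.fragment)
            rows.append(np.concatenate([
                state_rep, self.frag_reps[a.fragment],
                g.atom_features[a.scaffold_atom],
                frag.graph.atom_features[a.fragment_atom]]))
        mat = (np.vstack(rows) if rows
               else np.zeros((0, 2 * len(state_rep))))
        return state_rep, mat

    def _logits(self, stop_feat: np.ndarray, action_mat: np.ndarray) -> nn.Tensor:
        stop_logit = self.stop_mlp(nn.Tensor(stop_feat[None, :])).reshape(1)
        if len(action_mat) == 0:
            return stop_logit
        act_logits = self.action_mlp(nn.Tensor(action_mat)).reshape(-1)
        return nn.concat([stop_logit, act_logits])

    def action_distribution(self, state: GenerationState):
        actions = valid_actions(state, self.library,
                                self.config.symmetry_reduce)
        stop_feat, mat = self._features(state, actions)
        logp = self._logits(stop_feat, mat).log_softmax()
        return actions, np.exp(logp.data), (stop_feat, mat)


@dataclass
class Episode:
    final_state: GenerationState
    reward: float
    steps: list  # list of (stop_feat, action_mat, chosen_index, old_logp)


def rollout(policy: Policy, scaffold: str, reward_config: RewardConfig,
            rng: np.random.Generator) -> Episode:
    state = init_state(scaffold)
    steps = []
    while not state.terminated and state.step_count < reward_config.max_steps:
        actions, probs, feats = policy.action_distribution(state)
        k = int(rng.choice(len(actions), p=probs))
        steps.append((feats[0], feats[1], k, float(np.log(probs[k] + 1e-30))))
        state = apply_action(state, actions[k], policy.library)
    if not state.terminated:  # max-step cutoff
        state = apply_action(state, STOP, policy.library)
    reward = composite_reward(state.mol, reward_config,
                              steps=state.step_count)
    return Episode(final_state=state, reward=reward, steps=steps)


def train_policy(library, scaffold: str, init,
                 reward_config: RewardConfig | None = None,
                 rl_config: RLConfig | None = None):
    """Clipped policy-gradient training; returns ``(policy, history)``.

    ``init`` is an encoder checkpoint path, a :class:`HybridEncoder`, or
    ``None`` for a randomly initialized encoder (the no-pretraining
    baseline).  ``history`` holds the mean terminal reward per training
    iteration (one iteration = one batch of episodes).
    """
    if not library:
        raise ValueError("fragment library must be non-empty")
    reward_config = reward_config or RewardConfig()
    rl_config = rl_config or RLConfig()
    if (reward_config.step_penalty == 0 and not any(
            [reward_config.w_qed, reward_config.w_sa, reward_config.w_filter,
             reward_config.w_external])):
        logger.warning("all reward weights and the step penalty are zero: "
                       "the objective is degenerate")
    if isinstance(init, HybridEncoder):
        encoder = init
    elif init is None:
        from .encoder import EncoderConfig
        encoder = HybridEncoder(EncoderConfig(seed=rl_config.seed))
    else:
        encoder = HybridEncoder.load(init)
    policy = Policy(encoder, library, rl_config)
    opt = nn.Adam([(policy.params, rl_config.learning_rate)])
    rng = np.random.default_rng(rl_config.seed)
    history = []
    baseline = None
    n_iters = int(np.ceil(rl_config.episodes / rl_config.batch_episodes))
    for _it in range(n_iters):
        episodes = [rollout(policy, scaffold, reward_config, rng)
                    for _ in range(rl_config.batch_episodes)]
        rewards = np.array([e.reward for e in episodes])
        mean_r = float(rewards.mean())
        baseline = (mean_r if baseline is None else
                    rl_config.baseline_momentum * baseline
                    + (1 - rl_config.baseline_momentum) * mean_r)
        history.append(mean_r)
        flat = [(sf, mat, k, lp, e.reward - baseline)
                for e in episodes for (sf, mat, k, lp) in e.steps]
        if not flat:
            continue
        for _u in range(rl_config.update_epochs):
            objs, entropies = [], []
            for sf, mat, k, old_lp, adv in flat:
                logp_all = policy._logits(sf, mat).log_softmax()
                logp = logp_all.rows([k])
                ratio = (logp - old_lp).exp()
                clipped = ratio.clamp(1 - rl_config.clip, 1 + rl_config.clip)
                objs.append((ratio * adv).minimum(clipped * adv))
                entropies.append(-(logp_all.exp() * logp_all).sum(keepdims=True))
            loss = -(nn.concat(objs).mean()
                     + rl_config.entropy_coef * nn.concat(entropies).mean())
            opt.zero_grad()
            loss.backward()
            opt.step()
    return policy, history


@dataclass
class GenerationResult:
    smiles: str
    route: list  # list[RouteStep]
    state: GenerationState


def generate(policy: Policy, n: int, seed: int = 0,
             reward_config: RewardConfig | None = None,
             scaffold: str | None = None) -> list:
    """Sample ``n`` molecules (with routes) from the policy.

    Every returned molecule sanitizes: intermediate states are valence-masked
    at construction, so validity is 1.0 for any policy and seed.
    """
    reward_config = reward_config or RewardConfig()
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        ep = rollout(policy, scaffold or "c1ccccc1", reward_config, rng)
        out.append(GenerationResult(smiles=ep.final_state.smiles,
                                    route=list(ep.final_state.route),
                                    state=ep.final_state))
    return out


def replay_route(scaffold: str, route, library) -> str:
    """Rebuild a molecule from its recorded route; returns canonical SMILES."""
    state = init_state(scaffold)
    for step in route:
        action = Action(False, step.fragment, step.scaffold_atom,
                        step.fragment_atom)
        state = apply_action(state, action, library)
    return state.smiles


def export_routes(results) -> list:
    """Per-molecule disconnection lists (reverse of formation order).

    Each disconnection names the formed bond's two atoms in the final
    molecule's canonical atom numbering.
    """
    docs = []
    for res in results:
        mol = res.state.mol
        pos = canonical_atom_order(mol)
        disconnections = []
        for step in reversed(res.route):
            i = step.scaffold_atom
            j = step.n_atoms_before + step.fragment_atom
            disconnections.append({
                "fragment": step.fragment,
                "atom_i": pos[i], "atom_j": pos[j],
                "bond_order": step.bond_order,
            })
        docs.append({"smiles": Chem.MolToSmiles(mol),
                     "scaffold": res.state.scaffold_smiles,
                     "n_steps": len(res.route),
                     "disconnections": disconnections})
    return docs
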