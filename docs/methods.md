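# Methods

This note records the models, the parameter choices that matter, and what
the synthetic fixtures do and do not establish.

## Reaction centers from atom maps

A bond is identified across the reaction arrow by the unordered pair of
atom-map numbers of its endpoints — the only cross-side identity the format
guarantees.  A map pair present on one side and absent on the other is a
formed/broken bond; a pair present on both sides with different bond order
is recorded as broken *plus* formed.  Only heavy-atom bonds are considered;
implicit-hydrogen count changes are not treated as bond changes.  Reactants
with no mapped atoms (spectators/reagents, common in USPTO entries) are
retained in parsing and contribute no changes.  `map_complete` requires
every product atom mapped, unique maps per side, and product maps a subset
of reactant maps; `changed_bonds` refuses incomplete mappings rather than
guessing.

Note the subset requirement makes the formed/broken symmetry under side
swapping hold only for mass-balanced reactions; a condensation whose water
is dropped from the product cannot be read in reverse.

## Positive views

Graph-level augmentations: node deletion and attribute masking remove or
mask `⌊f·n⌋` atoms, bond deletion removes `round(f·m)` bonds (rounded so a
large fraction on a one-bond molecule deletes it), subgraph sampling grows a
connected induced subgraph by seeded random walk to `⌈f·n⌉` atoms.  Default
fractions 0.15 (0.8 for subgraph), common graph-contrastive practice.
Augmented views are encoder inputs, not claimed chemical structures: they
carry no RDKit molecule and no canonical SMILES.

Bond-level views: candidate disconnections are located by a SMARTS rule
library (packaged, user-replaceable) covering acyclic C–N/C–O/C–S single
bonds, amide, ester, ether and sulfonamide linkages, and acyclic C=C —
the polar, reaction-prone bonds a retrosynthetic analysis targets first.
A bond view is described by a 10-component local-environment vector: counts
of aromatic bonds, nitrogens, oxygens and ring bonds within a bond-count
radius of the endpoints (endpoints and the central bond excluded from their
own counts), plus central bond order, conjugation flag, ring flag, endpoint
electronegativity difference and sorted heavy-atom degrees.  Default radius
2: it captures the α/β environment (e.g. a carbonyl next to an ester
oxygen) without leaking the whole graph into the local descriptor.  When a
molecule has fewer than two candidate disconnections, `bond_bond` pairing
falls back to `graph_graph` with a logged notice.

Whether a batch mixes graph/graph, bond/bond and graph/bond pairs is a
config list; the default cycles uniformly over all three.

## Encoder

A GIN-style trunk: atom features (element one-hot over {C,N,O,S,F,Cl,Br,I,P,
other}, degree one-hot, formal charge, aromaticity, ring flag, mask flag) →
linear → 3 message-passing layers `H ← MLP(A·H + H)`, sum aggregation, each
followed by parameter-free row layer-normalization, mean-pool readout to
d_h = 128.  The layer norm was added for numerical stability: unnormalized
contrastive training inflates representation norms by an order of magnitude,
which saturates any freshly initialized downstream head.  Because the norm
cancels constant shifts, the output bias of each message-passing MLP would
be a dead parameter and is removed.  Sum aggregation plus mean pooling makes
the representation exactly permutation-invariant (verified on 20 random
atom reorderings per fixture molecule).

Bond views share the graph trunk ("one tower"): the local bond descriptor
passes through a bias-free 2-layer perceptron and is fused with the graph
representation — concatenation + linear map by default; a `sum` mode exists
in which a zero bond descriptor reduces the bond-view representation exactly
to the graph representation.  The projection head is a 2-layer perceptron to
d_z = 64 with epsilon-guarded L2 normalization.

All trainable components run on a small reverse-mode autodiff layer over
NumPy arrays (`retrofrag.nn`), with scipy sparse block-diagonal adjacency
for batching; gradients are verified against central finite differences in
the test suite.  Checkpoints are `.npz` archives carrying weights plus the
full encoder config.

## Contrastive loss and pretraining

The loss is NT-Xent-like with the positive pair excluded from the
denominator (`as_written`, the default): negatives are the other samples'
opposite-view embeddings only.  This form is not bounded below by zero — it
is negative whenever the positive similarity exceeds the within-batch
negatives, as the perfectly aligned orthogonal-pair case (L = −2 at τ = 1,
N = 2) shows.  The standard convention that keeps the positive term in the
denominator (`include_positive`, always ≥ 0) is a documented variant; both
are tested against a brute-force double-loop oracle.  Default temperature
0.5, Adam at 1e-3, batch 16 — the pretraining rate is a package choice (the
1e-5/1e-4 rates in the fine-tuning stage are fine-tuning rates, not
pretraining rates).  Pretraining draws molecules from reaction products by
default (they carry the disconnection semantics); reactants or both are
config options.

## Bond-breakage fine-tuning

A single linear prediction layer with sigmoid on the fused bond-view
representation, cross-entropy loss, Adam with decoupled learning rates —
1e-5 for the trunk, 1e-4 for the head — weight decay 1e-4, batch 32, splits
8:1:1 grouped by source reaction so no molecule leaks across splits,
no early stopping (validation is monitoring only), multi-seed protocol with
mean ± sd test AUC.  The prediction layer is zero-initialized so every run
starts at chance loss and the early loss curve reflects representation
quality rather than the random head draw.  `init=None` trains the identical
architecture from random initialization — the no-pretraining baseline.

The desk-scale comparison protocol pretrains on the distinct graphs
underlying the classification records themselves (the classification data
are derived from the same corpus the contrastive stage sees, as in the
full-scale protocol) and compares *mean* training-loss curves over three
fine-tuning seeds: single-seed comparisons on a task this small are decided
by initialization luck in either direction.

## Generation

The MDP state is the current molecule; an action is STOP or a (fragment,
scaffold atom, fragment atom) triple forming one single bond.  The action
space is built by actually attaching and sanitizing every candidate, so
invalid actions never exist and sampled molecules are valid with probability
1 — validity is a structural guarantee, not a learned property.  Equivalent
attachment atoms are collapsed to automorphism-orbit representatives
(RDKit canonical ranks without tie-breaking); toggleable.  Max 8 steps
(keeps generated MW roughly in the 250–500 window), STOP always available.

The policy scores each masked action with a perceptron over the
(frozen, pretrained) encoder's state representation, the fragment
representation and the two attachment atoms' attribute rows; a second
perceptron scores STOP.  Output layers are zero-initialized so the initial
policy is uniform over valid actions.  Training is clipped policy gradient
(ratio clip 0.2, 2 update passes per batch of 10 episodes, entropy bonus
0.01) against an exponential moving-average reward baseline — a learned
critic adds variance-reduction machinery a 7-fragment problem does not
need.  Terminal reward: weights · (QED, (10−SA)/9 clipped to [0,1],
fraction of alert catalogs passed, external hook) − step penalty · steps.
The external hook is the integration point for docking scorers; a
deterministic hash-based stub ships for tests.

Every applied action appends a route step (fragment id, attachment atom
indices, bond order, molecule size before the step).  Atom indices are
stable under later additions, so replaying a route from the scaffold
reproduces the final molecule exactly; exported route documents list the
disconnections in reverse formation order with atoms renumbered into the
final molecule's canonical order.

## Evaluation

Uniqueness is distinct canonical SMILES over valid molecules; novelty is the
fraction of distinct valid canonical SMILES absent from the canonicalized
reference (an explicit input — no default reference is downloaded).  Alert
pass rates use RDKit's built-in Glaxo, SureChEMBL and PAINS catalogs and are
computed over valid canonical-unique molecules; "pass" means no alert
matches, so higher is better.  Properties: RDKit MolWt, Crippen LogP,
QED, and the Ertl–Schuffenhauer SA score from RDKit's contrib tree.
Bemis–Murcko scaffold diversity is distinct scaffolds / valid molecules,
acyclic molecules mapping to the empty scaffold (counted once).

## Synthetic fixtures

Toy reactions instantiate four condensation/substitution skeletons —
esterification, amide coupling, dehydrative ether formation,
Williamson-style substitution — with small alkyl/aryl substituent pools.
Both sides are built programmatically with consistent atom maps, so the
formed/broken annotation is exact by construction; optional unmapped
spectator amines emulate USPTO reagent noise.  The separable
bond-classification dataset labels true reaction-center bonds positive and
same-graph non-center bonds negative, then flips each label independently
with probability `0.5·exp(−effect²)`: at effect 0 labels are pure noise
(a linear model scores AUC ≈ 0.5), at effect 2 contamination is ≈ 0.9% and
a linear model on the raw bond descriptors exceeds AUC 0.95.  The Gaussian
form is a package choice; only the two endpoints are contractual.

What these fixtures do **not** show: real reaction corpora have mapping
errors, multi-bond and ring-forming reaction centers, stereochemistry and
condition/yield annotations, none of which are emulated.  Toy-scale
uniqueness of the generator depends on the 7-fragment library and is
reported, not asserted.  Desk-scale problem sizes used throughout — 50–1,000
reactions, 2,000-record datasets, 200 RL episodes, 1,000 samples — were
chosen so the full suite runs in minutes on one CPU; conclusions about
full-scale corpora (tens of thousands of reactions, hundreds of epochs)
do not follow from these runs.

## Known limitations

* Only single-bond formation between attachment atoms; route steps record a
  bond order field for future extension.
* The `as_written` loss can be negative; training curves are comparable
  within a variant, not across variants.
* The policy's flat action enumeration is exact but scales with
  sites × fragments × attachment atoms; large libraries would need
  factorized heads.
* Atom-mapping inference is out of scope: inputs must carry maps.
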