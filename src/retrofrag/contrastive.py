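"""Contrastive pretraining: NT-Xent-style loss and training loop.

The loss contrasts each positive pair (two views of one molecule) against the
other pairs in the batch.  With unit embeddings z^1, z^2 and temperature τ,

    l_i = −log [ exp(⟨z_i^1, z_i^2⟩/τ) / Σ_{k≠i} exp(⟨z_i^1, z_k^2⟩/τ) ]
          −log [ exp(⟨z_i^2, z_i^1⟩/τ) / Σ_{k≠i} exp(⟨z_i^2, z_k^1⟩/τ) ]
    L   = (1/N) Σ_i l_i

Note the denominator excludes the positive term (k ≠ i): this "as_written"
form can be negative.  The standard SimCLR convention, which keeps k = i in
the denominator and is bounded below by 0, is available as the
``include_positive`` variant.  Negatives are drawn only from the opposite
view within the batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .augment import AugmentConfig, make_positive_pair
from .encoder import HybridEncoder


class DegenerateBatchError(Exception):
    pass


@dataclass
class ContrastiveBatch:
    z1: np.ndarray  # (N, d_z), unit rows
    z2: np.ndarray

    def __post_init__(self):
        self.z1 = np.asarray(self.z1, dtype=np.float64)
        self.z2 = np.asarray(self.z2, dtype=np.float64)
        if self.z1.shape != self.z2.shape:
            raise ValueError("view embeddings must have matching shapes")


@dataclass
class ContrastiveConfig:
    temperature: float = 0.5
    denominator_variant: str = "as_written"  # | "include_positive"
    epochs: int = 20
    batch_size: int = 16
    learning_rate: float = 1e-3
    strategies: tuple = ("graph_graph", "bond_bond", "graph_bond")
    seed: int = 0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.batch_size < 2:
            raise ValueError("batch size must be >= 2")
        if self.denominator_variant not in ("as_written", "include_positive"):
            raise ValueError("unknown denominator variant")


def _nt_xent_tensor(z1: nn.Tensor, z2: nn.Tensor, temperature: float,
                    variant: str) -> nn.Tensor:
    n = z1.shape[0]
    if n < 2:
        raise DegenerateBatchError(
            "NT-Xent needs N >= 2 (the k≠i denominator is empty at N = 1)")
    S = (z1 @ z2.T) * (1.0 / temperature)  # S[i,k] = sim(z_i^1, z_k^2)/τ
    m = float(S.data.max())
    E = (S - m).exp()
    eye = np.eye(n)
    diag = (S * eye).sum(axis=1)  # S_ii
    mask = np.ones((n, n)) - eye if variant == "as_written" else np.ones((n, n))
    denom_rows = (E * mask).sum(axis=1)  # over k: sim(z_i^1, z_k^2)
    denom_cols = (E * mask).sum(axis=0)  # over k: sim(z_k^1, z_i^2)
    l_i = (denom_rows.log() + m - diag) + (denom_cols.log() + m - diag)
    return l_i.mean()


def nt_xent_loss(batch: ContrastiveBatch,
                 config: ContrastiveConfig | None = None) -> float:
    """Mean NT-Xent loss of a batch of aligned positive-pair embeddings."""
    config = config or ContrastiveConfig()
    out = _nt_xent_tensor(nn.Tensor(batch.z1), nn.Tensor(batch.z2),
                          config.temperature, config.denominator_variant)
    return float(out.data)


def pretrain(molecules, encoder: HybridEncoder | None = None,
             augment_config: AugmentConfig | None = None,
             config: ContrastiveConfig | None = None,
             checkpoint_path=None):
    """Contrastive pretraining over a molecule set.

    Per epoch the molecules are shuffled into batches; each molecule yields a
    positive pair under a seeded randomly-chosen strategy from
    ``config.strategies``, both views are encoded and projected, and one Adam
    step is taken on the batch loss.  Returns ``(encoder, loss_history)`` with
    one mean loss per epoch.  Deterministic for a fixed seed.
    """
    molecules = list(molecules)
    if len(molecules) < 2:
        raise ValueError("pretraining needs at least 2 molecules")
    config = config or ContrastiveConfig()
    augment_config = augment_config or AugmentConfig()
    if encoder is None:
        from .encoder import EncoderConfig
        encoder = HybridEncoder(EncoderConfig(seed=config.seed))
    opt = nn.Adam([(encoder.params, config.learning_rate)])
    rng = np.random.default_rng(config.seed)
    history = []
    for _epoch in range(config.epochs):
        order = rng.permutation(len(molecules))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            if len(idx) < 2:
                continue
            views1, views2 = [], []
            for k in idx:
                strategy = config.strategies[
                    int(rng.integers(len(config.strategies)))]
                pair = make_positive_pair(molecules[k], strategy,
                                          int(rng.integers(2 ** 31)),
                                          augment_config)
                views1.append(pair.view1)
                views2.append(pair.view2)
            z1 = encoder.project(encoder.encode_views(views1))
            z2 = encoder.project(encoder.encode_views(views2))
            loss = _nt_xent_tensor(z1, z2, config.temperature,
                                   config.denominator_variant)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
    if checkpoint_path is not None:
        encoder.save(checkpoint_path)
    return encoder, history


def embed_pairs(encoder: HybridEncoder, molecules, config: ContrastiveConfig,
                augment_config: AugmentConfig | None = None, seed: int = 0):
    """Embed one positive pair per molecule (no training); returns (z1, z2)."""
    augment_config = augment_config or AugmentConfig()
    rng = np.random.default_rng(seed)
    views1, views2 = [], []
    for g in molecules:
        strategy = config.strategies[int(rng.integers(len(config.strategies)))]
        pair = make_positive_pair(g, strategy, int(rng.integers(2 ** 31)),
                                  augment_config)
        views1.append(pair.view1)
        views2.append(pair.view2)
    z1 = encoder.project(encoder.encode_views(views1)).data
    z2 = encoder.project(encoder.encode_views(views2)).data
    return z1, z2
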