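"""Hybrid graph / local-bond-feature encoder and projection head.

The encoder has a GIN-style message-passing trunk over atom-attribute vectors
(sum aggregation, mean-pool readout — permutation invariant by construction),
a small perceptron branch over the local bond-environment descriptor, and a
fusion map producing one representation space for both whole-graph views and
bond views.  A two-layer projection head maps representations to the
unit-normalized embedding space where the contrastive loss operates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import sparse

from . import nn
from .augment import BOND_FEATURE_LENGTH, BondView
from .chem import MolecularGraph, N_ATOM_FEATURES


class EncodingError(Exception):
    pass


@dataclass
class EncoderConfig:
    n_layers: int = 3
    d_h: int = 128
    d_z: int = 64
    bond_hidden: int = 64
    fusion: str = "concat"  # "concat" | "sum"
    atom_feature_len: int = N_ATOM_FEATURES
    bond_feature_len: int = BOND_FEATURE_LENGTH
    seed: int = 0

    def __post_init__(self):
        if min(self.n_layers, self.d_h, self.d_z, self.bond_hidden) < 1:
            raise ValueError("all widths and depths must be >= 1")
        if self.fusion not in ("concat", "sum"):
            raise ValueError("fusion must be 'concat' or 'sum'")


def _rownorm(h: nn.Tensor, eps: float = 1e-6) -> nn.Tensor:
    mu = h.mean(axis=-1, keepdims=True)
    centered = h - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    return centered * ((var + eps) ** -0.5)


def _batch_arrays(graphs):
    """Concatenate graphs into (features, block adjacency, mean-pool matrix)."""
    sizes = [g.n_atoms for g in graphs]
    if any(s == 0 for s in sizes):
        raise EncodingError("cannot encode an empty graph")
    total = sum(sizes)
    X = np.vstack([g.atom_features for g in graphs])
    rows, cols = [], []
    offset = 0
    for g in graphs:
        for i, j, _ in g.bonds:
            rows += [offset + i, offset + j]
            cols += [offset + j, offset + i]
        offset += g.n_atoms
    A = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)),
                          shape=(total, total))
    prow, pcol, pval = [], [], []
    offset = 0
    for b, s in enumerate(sizes):
        prow += [b] * s
        pcol += list(range(offset, offset + s))
        pval += [1.0 / s] * s
        offset += s
    P = sparse.csr_matrix((pval, (prow, pcol)), shape=(len(graphs), total))
    return X, A, P


class HybridEncoder:
    """f (representations) and g (projection head) of the contrastive model."""

    def __init__(self, config: EncoderConfig | None = None):
        self.config = config or EncoderConfig()
        c = self.config
        rng = np.random.default_rng(c.seed)
        self.input_lin = nn.Linear(c.atom_feature_len, c.d_h, rng)
        self.gin_layers = [nn.MLP([c.d_h, c.d_h, c.d_h], rng)
                           for _ in range(c.n_layers)]
        for mlp in self.gin_layers:
            # the row normalization after each layer cancels a constant
            # shift, so the output bias would be a dead parameter
            mlp.layers[-1].b = None
        # bias-free so a zero bond-feature vector contributes nothing under
        # "sum" fusion (encode_bond_view then equals encode_graph)
        self.bond_mlp = nn.MLP([c.bond_feature_len, c.bond_hidden, c.d_h],
                               rng, bias=False)
        self.fuse_lin = (nn.Linear(2 * c.d_h, c.d_h, rng)
                         if c.fusion == "concat" else None)
        self.proj = nn.MLP([c.d_h, c.d_h, c.d_z], rng)

    # ---- parameters --------------------------------------------------------
    @property
    def trunk_params(self):
        ps = self.input_lin.params[:]
        for layer in self.gin_layers:
            ps += layer.params
        ps += self.bond_mlp.params
        if self.fuse_lin is not None:
            ps += self.fuse_lin.params
        return ps

    @property
    def params(self):
        return self.trunk_params + self.proj.params

    # ---- encoding ----------------------------------------------------------
    def encode_graphs(self, graphs) -> nn.Tensor:
        """(B, d_h) representations; permutation-invariant per graph."""
        X, A, P = _batch_arrays(graphs)
        H = self.input_lin(nn.Tensor(X)).relu()
        for k, layer in enumerate(self.gin_layers):
            # parameter-free layer norm keeps the representation scale
            # stable through pretraining (no batch statistics, so encoding
            # stays deterministic and batch-size independent)
            H = _rownorm(layer(nn.spmm(A, H) + H))
            if k < len(self.gin_layers) - 1:
                H = H.relu()
        return nn.spmm(P, H)

    def encode_graph(self, graph: MolecularGraph) -> np.ndarray:
        return self.encode_graphs([graph]).data[0]

    def _fuse(self, h: nn.Tensor, bond_feats: np.ndarray) -> nn.Tensor:
        if bond_feats.shape[1] != self.config.bond_feature_len:
            raise EncodingError(
                f"bond feature length {bond_feats.shape[1]} does not match "
                f"config ({self.config.bond_feature_len})")
        b = self.bond_mlp(nn.Tensor(bond_feats))
        if self.config.fusion == "sum":
            return h + b
        return self.fuse_lin(nn.concat([h, b], axis=1))

    def encode_bond_views(self, views) -> nn.Tensor:
        uniq, index = [], {}
        for v in views:
            if id(v.graph) not in index:
                index[id(v.graph)] = len(uniq)
                uniq.append(v.graph)
        H = self.encode_graphs(uniq)
        h = H.rows([index[id(v.graph)] for v in views])
        feats = np.vstack([v.features for v in views])
        return self._fuse(h, feats)

    def encode_bond_view(self, view: BondView) -> np.ndarray:
        return self.encode_bond_views([view]).data[0]

    def encode_views(self, views) -> nn.Tensor:
        """Mixed list of MolecularGraph and BondView, batched, order kept."""
        graph_ix = [k for k, v in enumerate(views)
                    if isinstance(v, MolecularGraph)]
        bond_ix = [k for k, v in enumerate(views) if isinstance(v, BondView)]
        parts, order = [], []
        if graph_ix:
            parts.append(self.encode_graphs([views[k] for k in graph_ix]))
            order += graph_ix
        if bond_ix:
            parts.append(self.encode_bond_views([views[k] for k in bond_ix]))
            order += bond_ix
        H = parts[0] if len(parts) == 1 else nn.concat(parts, axis=0)
        inverse = np.argsort(order)
        return H.rows(inverse)

    def project(self, h: nn.Tensor) -> nn.Tensor:
        """Embeddings z with unit L2 norm (epsilon-guarded)."""
        return self.proj(h).l2_normalize()

    # ---- persistence -------------------------------------------------------
    def save(self, path):
        arrays = {f"p{i}": p.data for i, p in enumerate(self.params)}
        np.savez(path, __config__=json.dumps(asdict(self.config)), **arrays)

    @classmethod
    def load(cls, path) -> "HybridEncoder":
        with np.load(path, allow_pickle=False) as f:
            config = EncoderConfig(**json.loads(str(f["__config__"])))
            enc = cls(config)
            for i, p in enumerate(enc.params):
                arr = f[f"p{i}"]
                if arr.shape != p.data.shape:
                    raise EncodingError("checkpoint/config shape mismatch")
                p.data = arr.astype(np.float64)
        return enc
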