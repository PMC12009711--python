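"""Bond-breakage classification: fine-tuning the pretrained encoder.

A single linear prediction layer with a sigmoid is placed on the fused
bond-view representation and trained with cross-entropy under two learning
rates — a small one for the encoder trunk, a larger one for the head — so the
pretrained representation is adapted gently while the head fits quickly.
Passing ``init=None`` trains from a randomly initialized encoder: the
no-pretraining baseline.  Splits are grouped by source reaction so no
molecule contributes bonds to more than one split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from . import nn
from .augment import BondView
from .chem import BondLabelRecord, MolecularGraph
from .encoder import EncoderConfig, HybridEncoder


class DataError(Exception):
    pass


class MetricError(Exception):
    pass


@dataclass
class FinetuneConfig:
    encoder_lr: float = 1e-5
    head_lr: float = 1e-4
    weight_decay: float = 1e-4
    batch_size: int = 32
    epochs: int = 200
    split_ratios: tuple = (0.8, 0.1, 0.1)
    seeds: tuple = tuple(range(10))
    radius: int = 2
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")
        if min(self.encoder_lr, self.head_lr) <= 0:
            raise ValueError("learning rates must be > 0")


def split_dataset(records, ratios=(0.8, 0.1, 0.1), seed: int = 0):
    """Grouped train/valid/test split: all bonds of a reaction stay together."""
    if not records:
        raise DataError("no records to split")
    groups = sorted({r.reaction_index for r in records})
    if len(groups) < 3:
        raise DataError("need at least 3 source reactions to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(groups))
    n = len(groups)
    n_train = int(round(ratios[0] * n))
    n_valid = int(round(ratios[1] * n))
    n_train = max(1, min(n_train, n - 2))
    n_valid = max(1, min(n_valid, n - n_train - 1))
    sets = (set(groups[k] for k in order[:n_train]),
            set(groups[k] for k in order[n_train:n_train + n_valid]),
            set(groups[k] for k in order[n_train + n_valid:]))
    splits = tuple([r for r in records if r.reaction_index in s] for s in sets)
    if any(not s for s in splits):
        raise DataError("too few reactions to populate all splits")
    return splits


def auc(labels, scores) -> float:
    """ROC AUC (Mann–Whitney formulation, ties counted half)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise MetricError("AUC needs both classes present")
    return float(roc_auc_score(labels, scores))


class BondClassifier:
    """Encoder trunk + linear prediction layer with sigmoid output."""

    def __init__(self, encoder: HybridEncoder, radius: int = 2,
                 head_seed: int = 0):
        self.encoder = encoder
        self.radius = radius
        rng = np.random.default_rng(head_seed)
        self.head = nn.Linear(encoder.config.d_h, 1, rng)
        # zero-init the prediction layer so every run starts at chance loss
        # and the early loss curve reflects representation quality, not the
        # random head draw
        self.head.W.data[:] = 0.0
        self.head.b.data[:] = 0.0

    def _views(self, records):
        return [BondView(r.graph, r.bond_index, self.radius) for r in records]

    def _logits(self, views) -> nn.Tensor:
        h = self.encoder.encode_bond_views(views)
        return self.head(h).reshape(-1)

    def predict_views(self, views) -> np.ndarray:
        return self._logits(views).sigmoid().data

    def predict_records(self, records) -> np.ndarray:
        return self.predict_views(self._views(records))


def predict_bond_breakage(classifier: BondClassifier, graph: MolecularGraph,
                          bond_index: int) -> float:
    """Probability in [0, 1] that the given bond is a reaction-center bond."""
    view = BondView(graph, bond_index, classifier.radius)
    return float(classifier.predict_views([view])[0])


def _labels(records) -> np.ndarray:
    labels = set(r.label for r in records)
    if not labels <= {"altered", "unaltered"}:
        raise DataError(f"non-binary label set: {labels}")
    return np.array([1.0 if r.label == "altered" else 0.0 for r in records])


def finetune(init, train_records, valid_records,
             config: FinetuneConfig | None = None, seed: int | None = None):
    """Train the breakage classifier; returns ``(classifier, history)``.

    ``init`` is a checkpoint path, a :class:`HybridEncoder`, or ``None`` for
    the randomly initialized baseline.  ``history`` has one dict per epoch
    with train loss and validation AUC.
    """
    config = config or FinetuneConfig()
    seed = config.seed if seed is None else seed
    if isinstance(init, HybridEncoder):
        encoder = init
    elif init is None:
        encoder = HybridEncoder(EncoderConfig(seed=seed))
    else:
        encoder = HybridEncoder.load(init)
    clf = BondClassifier(encoder, radius=config.radius, head_seed=seed + 1)
    y_train = _labels(train_records)
    y_valid = _labels(valid_records) if valid_records else None
    train_views = clf._views(train_records)
    valid_views = clf._views(valid_records) if valid_records else None

    opt = nn.Adam([(encoder.trunk_params, config.encoder_lr),
                   (clf.head.params, config.head_lr)],
                  weight_decay=config.weight_decay)
    rng = np.random.default_rng(seed)
    history = []
    eps = 1e-12
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_views))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            views = [train_views[k] for k in idx]
            y = nn.Tensor(y_train[idx])
            p = clf._logits(views).sigmoid()
            loss = -(y * (p + eps).log()
                     + (1.0 - y) * (1.0 - p + eps).log()).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if valid_views is not None and y_valid is not None and len(
                np.unique(y_valid)) == 2:
            entry["valid_auc"] = auc(y_valid, clf.predict_views(valid_views))
        history.append(entry)
    return clf, history


def distinct_graphs(records):
    """The distinct molecular graphs underlying a record list (by identity).

    Pretraining uses these as its unlabeled corpus: the classification
    dataset is derived from the same reactions the contrastive stage sees,
    mirroring the derived-dataset fine-tuning protocol.
    """
    seen, out = set(), []
    for r in records:
        if id(r.graph) not in seen:
            seen.add(id(r.graph))
            out.append(r.graph)
    return out


def finetune_protocol(records, init_factory, config: FinetuneConfig | None = None):
    """Multi-seed protocol: split, fine-tune and evaluate per seed.

    ``init_factory(seed)`` supplies the encoder initialization for each run
    (e.g. a loaded checkpoint, or ``None`` for the baseline).  Returns a list
    of per-seed dicts and the (mean, sd) of the test AUC.
    """
    config = config or FinetuneConfig()
    rows = []
    for s in config.seeds:
        train, valid, test = split_dataset(records, config.split_ratios, s)
        clf, history = finetune(init_factory(s), train, valid, config, seed=s)
        test_auc = auc(_labels(test), clf.predict_records(test))
        rows.append({"seed": s, "test_auc": test_auc,
                     "final_train_loss": history[-1]["train_loss"]})
    aucs = [r["test_auc"] for r in rows]
    return rows, (float(np.mean(aucs)), float(np.std(aucs)))
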