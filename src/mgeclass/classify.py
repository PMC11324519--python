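"""The two classification branches and their attention-based aggregation.

The marker branch is a gradient-boosted decision forest over the 25
gene-content features. The sequence branch is an alignment-free neural
classifier: a convolutional encoder produces a feature map from the
one-hot input, non-local patches of the map are pooled by attention into a
fixed-length embedding (trained first with a supervised contrastive loss),
and a dense head trained with a focal loss maps embeddings to class
scores. The aggregator weighs the two branches with an attention weight
that grows with the fraction of genes assigned to markers — when no gene
has a marker the marker branch contributes nothing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import xgboost as xgb

from . import nn
from .records import CLASSES, SequenceRecord

_NT_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def one_hot(seq: str, W: int) -> np.ndarray:
    """One-hot encode a nucleotide string into a W×4 matrix.

    A/C/G/T map to unit rows; N (and any ambiguity) maps to a zero row;
    sequences shorter than W are zero-padded on the right. Longer
    sequences must be windowed by the caller.
    """
    if W <= 0:
        raise ValueError("W must be positive")
    if not seq:
        raise ValueError("empty sequence")
    out = np.zeros((W, 4))
    for i, c in enumerate(seq[:W]):
        j = _NT_INDEX.get(c)
        if j is not None:
            out[i, j] = 1.0
    return out


# ---------------------------------------------------------------------------
# marker branch (gradient-boosted decision forest)

XGB_DEFAULTS = {"eta": 0.2, "max_depth": 10, "n_estimators": 135}


@dataclass
class MarkerBranchModel:
    booster: xgb.Booster
    feature_registry: tuple[str, ...]
    class_order: tuple[str, ...] = CLASSES

    def predict(self, X: np.ndarray) -> np.ndarray:
        if X.shape[1] != len(self.feature_registry):
            raise ValueError("feature matrix does not match the model's registry")
        scores = self.booster.predict(xgb.DMatrix(X))
        return scores / scores.sum(axis=1, keepdims=True)

    def save(self, path: str | Path) -> None:
        raw = self.booster.save_raw("json").decode()
        payload = {
            "kind": "marker_branch",
            "feature_registry": list(self.feature_registry),
            "class_order": list(self.class_order),
            "booster": raw,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "MarkerBranchModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("kind") != "marker_branch":
            raise ValueError(f"{path} is not a marker-branch model file")
        booster = xgb.Booster()
        booster.load_model(bytearray(payload["booster"].encode()))
        return cls(
            booster=booster,
            feature_registry=tuple(payload["feature_registry"]),
            class_order=tuple(payload["class_order"]),
        )


def train_marker_branch(
    X: np.ndarray,
    y: Sequence[int],
    feature_registry: Sequence[str],
    params: dict | None = None,
    seed: int = 0,
) -> MarkerBranchModel:
    """Fit the decision-forest marker branch (deterministic given seed)."""
    y = np.asarray(y)
    if set(np.unique(y)) != {0, 1, 2}:
        missing = [CLASSES[c] for c in range(3) if c not in set(y.tolist())]
        raise ValueError(f"training labels missing classes: {missing}")
    merged = dict(XGB_DEFAULTS)
    if params:
        merged.update(params)
    n_rounds = int(merged.pop("n_estimators"))
    merged.update(
        {
            "objective": "multi:softprob",
            "num_class": 3,
            "seed": seed,
            "nthread": 1,
            "tree_method": "hist",
        }
    )
    dtrain = xgb.DMatrix(X, label=y)
    booster = xgb.train(merged, dtrain, num_boost_round=n_rounds)
    return MarkerBranchModel(booster=booster, feature_registry=tuple(feature_registry))


# ---------------------------------------------------------------------------
# sequence branch (conv encoder + patch attention + contrastive training)


@dataclass
class SequenceBranchConfig:
    window: int = 6000
    channels: int = 64
    n_layers: int = 4
    kernel: int = 5
    stride: int = 2
    n_patches: int = 64
    patch_size: int = 4
    dim: int = 128
    proj_dim: int = 64
    clf_hidden: int = 32
    temperature: float = 0.1
    focal_gamma: float = 2.0
    contrastive_epochs: int = 20
    classifier_epochs: int = 60
    batch_size: int = 64
    lr: float = 1e-3


class SequenceBranchModel:
    """Convolutional encoder with patch-attention pooling plus dense head."""

    def __init__(self, config: SequenceBranchConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.convs: list[nn.Conv1D] = []
        self.relus: list[nn.ReLU] = []
        c_in, L = 4, config.window
        for i in range(config.n_layers):
            conv = nn.Conv1D(c_in, config.channels, config.kernel, config.stride, rng, name=f"conv{i}")
            self.convs.append(conv)
            self.relus.append(nn.ReLU())
            L = conv.out_length(L)
            c_in = config.channels
        if L < config.patch_size:
            raise ValueError("window too short for the conv stack")
        self.pool = nn.PatchAttentionPool(
            L, config.channels, config.n_patches, config.patch_size, config.dim, rng
        )
        self.proj = nn.MLP([config.dim, config.dim, config.proj_dim], rng, name="proj")
        self.clf = nn.MLP([config.dim, config.clf_hidden, 3], rng, name="clf")

    @property
    def encoder_params(self) -> list[nn.Param]:
        out = []
        for conv in self.convs:
            out.extend(conv.params)
        out.extend(self.pool.params)
        return out

    def encode(self, X: np.ndarray) -> np.ndarray:
        h = X
        for conv, relu in zip(self.convs, self.relus):
            h = relu.forward(conv.forward(h))
        return self.pool.forward(h)

    def encode_backward(self, de: np.ndarray) -> None:
        dh = self.pool.backward(de)
        for conv, relu in zip(reversed(self.convs), reversed(self.relus)):
            dh = conv.backward(relu.backward(dh))

    def predict_windows(self, X: np.ndarray) -> np.ndarray:
        return nn.softmax(self.clf.forward(self.encode(X)))

    # -- serialization ------------------------------------------------------

    def _all_params(self) -> list[nn.Param]:
        return self.encoder_params + self.proj.params + self.clf.params

    def save(self, path: str | Path) -> None:
        payload = {
            "kind": "sequence_branch",
            "config": asdict(self.config),
            "state": nn.params_to_state(self._all_params()),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "SequenceBranchModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("kind") != "sequence_branch":
            raise ValueError(f"{path} is not a sequence-branch model file")
        model = cls(SequenceBranchConfig(**payload["config"]))
        nn.state_to_params(model._all_params(), payload["state"])
        return model


def train_sequence_branch(
    windows: np.ndarray,
    labels: Sequence[int],
    config: SequenceBranchConfig | None = None,
    seed: int = 0,
) -> SequenceBranchModel:
    """Two-step training: contrastive encoder, then focal-loss classifier.

    Step 1 minimizes the supervised contrastive loss on the projection-head
    outputs so same-class windows cluster in embedding space; batches that
    happen to contain a single class are skipped with a warning. Step 2
    freezes the encoder and trains the dense classifier head with a focal
    loss under Adam with gradient centralization. Fully seeded.
    """
    config = config or SequenceBranchConfig()
    labels = np.asarray(labels)
    model = SequenceBranchModel(config, seed=seed)
    rng = np.random.default_rng(seed + 1)
    n = windows.shape[0]

    opt = nn.Adam(model.encoder_params + model.proj.params, lr=config.lr)
    for _ in range(config.contrastive_epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            if len(idx) < 2:
                continue
            if len(np.unique(labels[idx])) < 2:
                warnings.warn("skipping single-class batch in contrastive step")
                continue
            e = model.encode(windows[idx])
            p = model.proj.forward(e)
            z, norm = nn.l2_normalize(p)
            _, dz = nn.supcon_loss(z, labels[idx], config.temperature)
            dp = nn.l2_normalize_backward(dz, z, norm)
            opt.zero_grad()
            de = model.proj.backward(dp)
            model.encode_backward(de)
            opt.step()

    # frozen encoder: embed once, then train the head
    emb = np.concatenate(
        [model.encode(windows[i : i + 256]) for i in range(0, n, 256)]
    )
    opt2 = nn.Adam(model.clf.params, lr=config.lr)
    for _ in range(config.classifier_epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = model.clf.forward(emb[idx])
            _, dlogits = nn.focal_loss(logits, labels[idx], config.focal_gamma)
            opt2.zero_grad()
            model.clf.backward(dlogits)
            opt2.step()
    return model


def score_sequence_branch(model: SequenceBranchModel, record: SequenceRecord) -> np.ndarray:
    """Score one sequence: tile into W windows, average window scores."""
    W = model.config.window
    seq = record.seq
    chunks = [seq[i : i + W] for i in range(0, len(seq), W)] or [seq]
    X = np.stack([one_hot(c, W) for c in chunks])
    scores = model.predict_windows(X).mean(axis=0)
    return scores / scores.sum()


def score_sequence_branch_batch(
    model: SequenceBranchModel, records: Sequence[SequenceRecord]
) -> np.ndarray:
    """Vectorized scoring: one-window records are batched together."""
    W = model.config.window
    out = np.zeros((len(records), 3))
    singles = [i for i, r in enumerate(records) if r.length <= W]
    multis = [i for i, r in enumerate(records) if r.length > W]
    for start in range(0, len(singles), 256):
        idx = singles[start : start + 256]
        X = np.stack([one_hot(records[i].seq, W) for i in idx])
        out[idx] = model.predict_windows(X)
    for i in multis:
        out[i] = score_sequence_branch(model, records[i])
    out /= out.sum(axis=1, keepdims=True)
    return out


# ---------------------------------------------------------------------------
# aggregator


class AggregatorModel:
    """Attention aggregation of the two branches.

    The marker-branch weight is w_m(f) = softplus(a)·f — zero at marker
    frequency 0 and non-decreasing by construction; the sequence branch
    carries a constant weight w_s = softplus(c). Scaled scores are averaged
    and passed through a dense softmax layer.
    """

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.a = nn.Param("agg.a", np.array(1.0))
        self.c = nn.Param("agg.c", np.array(1.0))
        self.A = nn.Param("agg.A", np.eye(3) * 4.0 + rng.normal(0, 0.01, (3, 3)))
        self.b = nn.Param("agg.b", np.zeros(3))

    @property
    def params(self) -> list[nn.Param]:
        return [self.a, self.c, self.A, self.b]

    @staticmethod
    def _softplus(x: float) -> float:
        return float(np.log1p(np.exp(-abs(x))) + max(x, 0.0))

    def weights(self, f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        f = np.asarray(f, dtype=float)
        w_m = self._softplus(float(self.a.value)) * f
        w_s = np.full_like(f, self._softplus(float(self.c.value)))
        return w_m, w_s

    def forward(
        self, seq_scores: np.ndarray, marker_scores: np.ndarray, freqs: np.ndarray
    ) -> np.ndarray:
        freqs = np.asarray(freqs, dtype=float)
        if freqs.min() < 0 or freqs.max() > 1:
            raise ValueError("marker_frequency outside [0, 1]")
        w_m, w_s = self.weights(freqs)
        z = (w_m[:, None] * marker_scores + w_s[:, None] * seq_scores) / 2.0
        return nn.softmax(z @ self.A.value + self.b.value)

    def save(self, path: str | Path) -> None:
        payload = {"kind": "aggregator", "state": nn.params_to_state(self.params)}
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "AggregatorModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("kind") != "aggregator":
            raise ValueError(f"{path} is not an aggregator model file")
        model = cls()
        nn.state_to_params(model.params, payload["state"])
        return model


def aggregate_scores(
    seq_scores: np.ndarray,
    marker_scores: np.ndarray,
    marker_frequency: float | np.ndarray,
    model: AggregatorModel,
) -> np.ndarray:
    """Combine branch scores for one sequence or a batch."""
    seq_scores = np.atleast_2d(seq_scores)
    marker_scores = np.atleast_2d(marker_scores)
    freqs = np.atleast_1d(np.asarray(marker_frequency, dtype=float))
    out = model.forward(seq_scores, marker_scores, freqs)
    return out[0] if out.shape[0] == 1 and np.isscalar(marker_frequency) else out


def train_aggregator(
    seq_scores: np.ndarray,
    marker_scores: np.ndarray,
    freqs: np.ndarray,
    labels: Sequence[int],
    seed: int = 0,
    epochs: int = 300,
    lr: float = 0.05,
) -> AggregatorModel:
    """Fit the aggregator by seeded full-batch gradient descent on CE."""
    labels = np.asarray(labels)
    model = AggregatorModel(seed=seed)
    opt = nn.Adam(model.params, lr=lr, centralize=False)
    freqs = np.asarray(freqs, dtype=float)
    n = len(labels)
    for _ in range(epochs):
        sa = 1.0 / (1.0 + np.exp(-float(model.a.value)))  # d softplus
        sc = 1.0 / (1.0 + np.exp(-float(model.c.value)))
        w_m, w_s = model.weights(freqs)
        z = (w_m[:, None] * marker_scores + w_s[:, None] * seq_scores) / 2.0
        logits = z @ model.A.value + model.b.value
        _, dlogits = nn.cross_entropy(logits, labels)
        opt.zero_grad()
        model.A.grad += z.T @ dlogits
        model.b.grad += dlogits.sum(axis=0)
        dz = dlogits @ model.A.value.T
        model.a.grad += np.array(
            np.sum(dz * marker_scores * freqs[:, None]) / 2.0 * sa
        )
        model.c.grad += np.array(np.sum(dz * seq_scores) / 2.0 * sc)
        opt.step()
    return model
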