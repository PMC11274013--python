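"""Convolutional encoder and its supervised pre-training on base classes.

The feature extractor f_theta maps a Mel/PCEN patch to a d-dimensional
embedding through four conv blocks (3x3 conv -> batch norm -> ReLU -> 2x2
max pool) with 64/128/256/512 filters, followed by global average pooling,
so d equals the last filter count. Pre-training is plain mini-batch
supervised classification of base-class patches with a linear head and
cross-entropy; an episodic prototypical regime is also provided for the
baseline detector, which is trained with its own recipe (lr 1e-4, halved
every 10 epochs).

Patches shorter than the cumulative pooling factor (2^n_blocks frames) are
tiled along time before entering the network.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import _nn
from .audio import tile_to_length
from .augment import AugmentConfig, augment


@dataclass
class EncoderConfig:
    n_blocks: int = 4
    filters: tuple[int, ...] = (64, 128, 256, 512)
    embedding_note: str = "d = last filter count after global average pooling"

    def __post_init__(self) -> None:
        self.filters = tuple(int(f) for f in self.filters)
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if len(self.filters) != self.n_blocks:
            raise ValueError("filters must list one width per block")
        if min(self.filters) <= 0:
            raise ValueError("filters must be strictly positive")

    @property
    def embedding_dim(self) -> int:
        return self.filters[-1]

    @property
    def min_input_frames(self) -> int:
        return 2 ** self.n_blocks


@dataclass
class TrainConfig:
    lr: float = 1e-3
    scheduler_gamma: float = 0.5
    scheduler_step: int = 5
    batch_size: int = 64
    epochs: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if not 0 < self.scheduler_gamma <= 1:
            raise ValueError("scheduler_gamma must be in (0, 1]")


def lr_at_epoch(cfg: TrainConfig, epoch: int) -> float:
    """Learning rate used during ``epoch`` (0-based): lr * gamma^(epoch//step)."""
    return cfg.lr * cfg.scheduler_gamma ** (epoch // cfg.scheduler_step)


@dataclass
class BaseDataset:
    """Labeled patches for pre-training: D_base = {X_base, Y_base}."""

    patches: np.ndarray          # [n, frames, n_mel]
    labels: np.ndarray           # [n] integer class ids
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.patches = np.asarray(self.patches, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.patches) != len(self.labels):
            raise ValueError("patches and labels must align")

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0


class Encoder:
    """The frozen-able feature extractor f_theta : patch -> R^d."""

    def __init__(self, cfg: EncoderConfig, seed: int = 0):
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.blocks: list[_nn.Sequential] = []
        c_in = 1
        for c_out in cfg.filters:
            self.blocks.append(_nn.Sequential([
                _nn.Conv3x3(c_in, c_out, rng),
                _nn.BatchNorm(c_out),
                _nn.ReLU(),
                _nn.MaxPool2x2(),
            ]))
            c_in = c_out
        self.gap = _nn.GlobalAvgPool()

    # -- plumbing -------------------------------------------------------
    @property
    def embedding_dim(self) -> int:
        return self.cfg.embedding_dim

    def params(self) -> list[_nn.Param]:
        return [p for b in self.blocks for p in b.params()]

    def _prepare(self, patches: np.ndarray) -> np.ndarray:
        patches = np.asarray(patches, dtype=np.float32)
        if patches.ndim == 2:
            patches = patches[None]
        if patches.ndim != 3:
            raise ValueError("patches must be [n, frames, bands]")
        need = self.cfg.min_input_frames
        if patches.shape[1] < need:
            patches = np.stack([tile_to_length(p, need) for p in patches])
        return patches[:, :, :, None]  # channels-last

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for b in self.blocks:
            x = b.forward(x, train)
        return self.gap.forward(x, train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self.gap.backward(grad)
        for b in reversed(self.blocks):
            grad = b.backward(grad)
        return grad

    def forward_until_last(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for b in self.blocks[:-1]:
            x = b.forward(x, train)
        return x

    def forward_last(self, acts: np.ndarray, train: bool = False) -> np.ndarray:
        x = self.blocks[-1].forward(acts, train)
        return self.gap.forward(x, train)

    def backward_last(self, grad: np.ndarray) -> np.ndarray:
        grad = self.gap.backward(grad)
        return self.blocks[-1].backward(grad)

    # -- public API -----------------------------------------------------
    def embed(self, patches: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Deterministic embeddings [n, d] (evaluation mode, running BN stats)."""
        x = self._prepare(patches)
        out = np.empty((len(x), self.embedding_dim), dtype=np.float64)
        for i in range(0, len(x), batch_size):
            out[i:i + batch_size] = self.forward(x[i:i + batch_size], train=False)
        return out


def build_encoder(cfg: EncoderConfig | None = None, seed: int = 0) -> Encoder:
    return Encoder(cfg or EncoderConfig(), seed)


def embed(e: Encoder, patches: np.ndarray) -> np.ndarray:
    return e.embed(patches)


def _augmented(patches: np.ndarray, aug: AugmentConfig | None,
               rng: np.random.Generator) -> np.ndarray:
    if aug is None:
        return patches
    from .augment import clamped
    aug = clamped(aug, patches.shape[1], patches.shape[2])
    return np.stack([augment(p, aug, rng) for p in patches])


def pretrain(e: Encoder, data: BaseDataset, cfg: TrainConfig,
             aug: AugmentConfig | None = None) -> list[float]:
    """Supervised pre-training with a linear head; returns per-epoch mean loss."""
    if data.n_classes < 2:
        raise ValueError("pre-training needs at least 2 base classes")
    rng = np.random.default_rng(cfg.seed)
    head = _nn.Linear(e.embedding_dim, data.n_classes, rng)
    opt = _nn.Adam(e.params() + head.params(), lr=cfg.lr)
    x_all = e._prepare(data.patches)[..., 0]  # tiled [n, frames, bands]
    history: list[float] = []
    for epoch in range(cfg.epochs):
        opt.lr = lr_at_epoch(cfg, epoch)
        order = rng.permutation(len(x_all))
        losses = []
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            if len(idx) < 2:
                continue  # batch norm needs >1 sample
            xb = _augmented(x_all[idx], aug, rng).astype(np.float32)[..., None]
            z = e.forward(xb, train=True)
            logits = head.forward(z, train=True)
            loss, dlogits = _nn.cross_entropy(logits, data.labels[idx])
            e.backward(head.backward(dlogits))
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return history


def training_accuracy(e: Encoder, head: _nn.Linear | None, data: BaseDataset) -> float:
    """Nearest-class-mean accuracy of the frozen encoder on its base data."""
    z = e.embed(data.patches)
    protos = np.stack([z[data.labels == k].mean(axis=0)
                       for k in range(data.n_classes)])
    d2 = ((z[:, None, :] - protos[None]) ** 2).sum(axis=2)
    return float(np.mean(d2.argmin(axis=1) == data.labels))


def pretrain_prototypical(e: Encoder, data: BaseDataset, *,
                          n_way: int = 2, k_shot: int = 5, n_query: int = 5,
                          episodes_per_epoch: int = 10, epochs: int = 10,
                          lr: float = 1e-4, scheduler_gamma: float = 0.5,
                          scheduler_step: int = 10, seed: int = 0) -> list[float]:
    """Episodic prototypical pre-training (the baseline system's recipe).

    Each episode samples ``n_way`` base classes; queries are classified by
    softmax over negative squared Euclidean distance to class prototypes and
    the episode cross-entropy is back-propagated through the encoder.
    """
    if data.n_classes < 2:
        raise ValueError("pre-training needs at least 2 base classes")
    rng = np.random.default_rng(seed)
    opt = _nn.Adam(e.params(), lr=lr)
    x_all = e._prepare(data.patches)[..., 0]
    by_class = [np.flatnonzero(data.labels == k) for k in range(data.n_classes)]
    way = min(n_way, data.n_classes)
    history: list[float] = []
    for epoch in range(epochs):
        opt.lr = lr * scheduler_gamma ** (epoch // scheduler_step)
        losses = []
        for _ in range(episodes_per_epoch):
            classes = rng.choice(data.n_classes, size=way, replace=False)
            sup_idx, qry_idx = [], []
            for k in classes:
                pool = by_class[k]
                take = rng.choice(pool, size=min(k_shot + n_query, len(pool)),
                                  replace=len(pool) < k_shot + n_query)
                sup_idx.append(take[:k_shot])
                qry_idx.append(take[k_shot:k_shot + max(1, len(take) - k_shot)])
            ns = sum(len(s) for s in sup_idx)
            batch = np.concatenate(sup_idx + qry_idx)
            xb = x_all[batch].astype(np.float32)[..., None]
            z = e.forward(xb, train=True).astype(np.float64)
            zs, zq = z[:ns], z[ns:]
            # prototypes per episode class, in episode order
            protos, owners = [], []
            off = 0
            for s in sup_idx:
                protos.append(zs[off:off + len(s)].mean(axis=0))
                owners.append((off, off + len(s)))
                off += len(s)
            protos = np.stack(protos)
            yq = np.concatenate([np.full(len(q), j) for j, q in enumerate(qry_idx)])
            diff = zq[:, None, :] - protos[None]           # [nq, way, d]
            logits = -(diff ** 2).sum(axis=2)
            p = _nn.softmax(logits)
            nq = len(zq)
            loss = -np.mean(np.log(np.maximum(p[np.arange(nq), yq], 1e-12)))
            g = p.copy()
            g[np.arange(nq), yq] -= 1.0
            g /= nq                                        # dL/dlogits
            dzq = -2.0 * (diff * g[:, :, None]).sum(axis=1)
            dproto = (2.0 * diff * g[:, :, None]).sum(axis=0)
            dzs = np.zeros_like(zs)
            for j, (a, b) in enumerate(owners):
                dzs[a:b] = dproto[j] / (b - a)
            dz = np.concatenate([dzs, dzq]).astype(np.float32)
            e.backward(dz)
            opt.step()
            losses.append(float(loss))
        history.append(float(np.mean(losses)))
    return history


# -- checkpoints ---------------------------------------------------------

def config_hash(cfg) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def save_encoder(e: Encoder, path) -> None:
    arrays = {}
    for i, p in enumerate(e.params()):
        arrays[f"param_{i}"] = p.value
    for bi, b in enumerate(e.blocks):
        bn = b.layers[1]
        arrays[f"bn_mean_{bi}"] = bn.running_mean
        arrays[f"bn_var_{bi}"] = bn.running_var
    meta = json.dumps({"version": 1, "seed": e.seed,
                       "config": asdict(e.cfg), "hash": config_hash(e.cfg)})
    np.savez(path, __meta__=np.array(meta), **arrays)


def load_encoder(path) -> Encoder:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        cfgd = meta["config"]
        cfg = EncoderConfig(n_blocks=cfgd["n_blocks"],
                            filters=tuple(cfgd["filters"]))
        e = Encoder(cfg, seed=meta.get("seed", 0))
        for i, p in enumerate(e.params()):
            p.value[...] = data[f"param_{i}"]
        for bi, b in enumerate(e.blocks):
            bn = b.layers[1]
            bn.running_mean[...] = data[f"bn_mean_{bi}"]
            bn.running_var[...] = data[f"bn_var_{bi}"]
    return e
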