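"""Shared fixtures: small encoders and a tiny trained detection setup.

Unit tests run on a narrow encoder (config-exposed widths) so the whole
suite stays fast; the acceptance tests use the full-width architecture.
"""

from __future__ import annotations

import numpy as np
import pytest

from timsed.audio import MelConfig, PcenConfig
from timsed.backbone import BaseDataset, EncoderConfig, TrainConfig, build_encoder, pretrain
from timsed.benchmark import make_benchmark_dataset
from timsed.events import build_base_dataset

SMALL_ENCODER = EncoderConfig(n_blocks=2, filters=(8, 16))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_encoder():
    return build_encoder(SMALL_ENCODER, seed=0)


def banded_patches(n_per_class: int, n_frames: int = 8, n_mel: int = 32,
                   seed: int = 0) -> BaseDataset:
    """Two synthetic classes with energy in disjoint Mel bands."""
    rng = np.random.default_rng(seed)
    patches, labels = [], []
    for label, band in ((0, slice(2, 8)), (1, slice(20, 26))):
        for _ in range(n_per_class):
            p = 0.05 * rng.random((n_frames, n_mel))
            p[:, band] += 1.0 + 0.2 * rng.random((n_frames, 6))
            patches.append(p)
            labels.append(label)
    return BaseDataset(np.stack(patches), np.array(labels), ["low", "high"])


@pytest.fixture(scope="session")
def tiny_setup(tmp_path_factory):
    """A small generated dataset plus an encoder trained on it.

    Shared across detection tests; everything derives from seed 0.
    """
    root = tmp_path_factory.mktemp("tiny_scenes")
    mel_cfg, pcen_cfg = MelConfig(), PcenConfig()
    manifest = make_benchmark_dataset(
        root, seed=0, n_train=2, n_val=2, train_duration_s=12.0,
        val_duration_s=25.0, train_events_per_class=4, val_events_per_class=8)
    pairs = sorted((w, w.with_suffix(".csv"))
                   for w in (root / "Training_Set").glob("*.wav"))
    data = build_base_dataset(pairs, mel_cfg, pcen_cfg, seed=0)
    enc = build_encoder(EncoderConfig(n_blocks=4, filters=(8, 16, 32, 64)), seed=0)
    pretrain(enc, data, TrainConfig(epochs=6, seed=0))
    return {"root": root, "encoder": enc, "manifest": manifest,
            "mel_cfg": mel_cfg, "pcen_cfg": pcen_cfg, "data": data}
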