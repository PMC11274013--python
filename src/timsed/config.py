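"""Layered run configuration: defaults < YAML file < command-line overrides."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .audio import MelConfig, PcenConfig
from .augment import AugmentConfig
from .backbone import EncoderConfig, TrainConfig
from .events import DetectionConfig
from .transductive import TimConfig


@dataclass
class DataConfig:
    """Synthetic dataset shape used by `timsed simulate`."""

    n_train: int = 4
    n_val: int = 2
    train_duration_s: float = 20.0
    val_duration_s: float = 45.0
    snr_db: float = 20.0
    train_events_per_class: int = 6
    val_events_per_class: int = 12


@dataclass
class RunConfig:
    mel: MelConfig = field(default_factory=MelConfig)
    pcen: PcenConfig = field(default_factory=PcenConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    tim: TimConfig = field(default_factory=lambda: TimConfig(l2_normalize=True))
    detect: DetectionConfig = field(default_factory=DetectionConfig)
    data: DataConfig = field(default_factory=DataConfig)
    iou_min: float = 0.3
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


class ConfigError(ValueError):
    pass


_SECTIONS = {
    "mel": MelConfig, "pcen": PcenConfig, "augment": AugmentConfig,
    "encoder": EncoderConfig, "train": TrainConfig, "tim": TimConfig,
    "detect": DetectionConfig, "data": DataConfig,
}


# Section defaults that differ from the dataclass's own: detection-facing
# TIM runs on L2-normalized logits (see transductive module docs).
_SECTION_DEFAULTS: dict[str, dict] = {"tim": {"l2_normalize": True}}


def _build_section(name: str, cls, values: dict):
    values = {**_SECTION_DEFAULTS.get(name, {}), **values}
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(values) - names
    if unknown:
        raise ConfigError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    if cls is EncoderConfig and "filters" in values:
        values = {**values, "filters": tuple(values["filters"])}
    try:
        return cls(**values)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"bad {cls.__name__}: {exc}") from exc


def load_config(path=None, overrides: list[str] = ()) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus `key.sub=value` overrides."""
    raw: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ConfigError(f"{path} must contain a mapping")
            raw = loaded
    for ov in overrides:
        if "=" not in ov:
            raise ConfigError(f"override {ov!r} must look like key.sub=value")
        key, value = ov.split("=", 1)
        parts = key.strip().split(".")
        node = raw
        for p in parts[:-1]:
            node = node.setdefault(p, {})
            if not isinstance(node, dict):
                raise ConfigError(f"override {ov!r} clashes with scalar {p!r}")
        node[parts[-1]] = yaml.safe_load(value)
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = raw.pop(name, {})
        if not isinstance(section, dict):
            raise ConfigError(f"section {name!r} must be a mapping")
        kwargs[name] = _build_section(name, cls, section)
    for scalar in ("iou_min", "seed"):
        if scalar in raw:
            kwargs[scalar] = raw.pop(scalar)
    if raw:
        raise ConfigError(f"unknown config sections: {sorted(raw)}")
    return RunConfig(**kwargs)
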