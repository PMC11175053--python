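"""Run configuration: one YAML/JSON file covering all four config blocks."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .augmentation import AugmentationConfig
from .model import BackboneConfig
from .synthetic_data import StreamSpec
from .training import TrainConfig

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclasses.dataclass
class RunConfig:
    train: TrainConfig = dataclasses.field(default_factory=TrainConfig)
    model: BackboneConfig = dataclasses.field(default_factory=BackboneConfig)
    augmentation: AugmentationConfig = dataclasses.field(default_factory=AugmentationConfig)
    stream: StreamSpec = dataclasses.field(default_factory=StreamSpec)


_SECTIONS = {
    "train": TrainConfig,
    "model": BackboneConfig,
    "augmentation": AugmentationConfig,
    "stream": StreamSpec,
}


def load_config(path: str | Path) -> RunConfig:
    """Read a config file; unknown keys are an error, missing ones default."""
    path = Path(path)
    raw = path.read_text()
    data = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
    data = data or {}
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = data.get(name, {}) or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        bad = set(section) - fields
        if bad:
            raise ValueError(f"unknown keys in [{name}]: {sorted(bad)}")
        if "strong_ops" in section:
            section["strong_ops"] = tuple(section["strong_ops"])
        kwargs[name] = cls(**section)
    return RunConfig(**kwargs)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    data = {name: dataclasses.asdict(getattr(cfg, name)) for name in _SECTIONS}
    data["augmentation"]["strong_ops"] = list(data["augmentation"]["strong_ops"])
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
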