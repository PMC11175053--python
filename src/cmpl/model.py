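"""Backbone networks for the teacher and student.

A small residual temporal CNN: a strided stem, stages of residual blocks,
global average pooling into the feature vector φ(x), and a linear head over
six classes (five behaviors plus the inactive class at index 5).  The 1D
layout convolves the 12 channels jointly; the 4D layout runs a shared
3-channel stem per sensor group and concatenates the sensor feature maps,
so the per-sensor (x, y, z) structure is explicit.

Depth presets trade accuracy for compute; ``small`` is the desk-scale
default and the larger presets follow the same block structure at greater
width/depth.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import nn
from ._autodiff import Tensor, softmax

__all__ = ["BackboneConfig", "ModelOutput", "Backbone", "build_model", "forward",
           "save_checkpoint", "load_checkpoint"]

N_CLASSES_TOTAL = 6  # 5 behaviors + inactive

_PRESETS: dict[str, dict] = {
    "small": {"stem": 16, "stages": [(16, 1), (32, 1)]},
    "resnet18-like": {"stem": 32, "stages": [(32, 2), (64, 2), (128, 2), (256, 2)]},
    "resnet30-like": {"stem": 32, "stages": [(32, 3), (64, 4), (128, 4), (256, 3)]},
    "resnet50-like": {"stem": 64, "stages": [(64, 3), (128, 4), (256, 6), (512, 3)]},
}


@dataclasses.dataclass(frozen=True)
class BackboneConfig:
    input_layout: str = "4d"  # "1d" (T, 12) or "4d" (T, 4, 3)
    preset: str = "small"
    feature_dim: int = 32
    n_classes: int = N_CLASSES_TOTAL

    def validate(self) -> None:
        if self.input_layout not in ("1d", "4d"):
            raise ValueError(f"unknown input layout {self.input_layout!r}")
        if self.preset not in _PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; choose from {sorted(_PRESETS)}")
        if self.feature_dim < 2:
            raise ValueError("feature_dim must be >= 2")
        if self.n_classes != N_CLASSES_TOTAL:
            raise ValueError(f"n_classes is fixed at {N_CLASSES_TOTAL}")


@dataclasses.dataclass
class ModelOutput:
    """Features φ(x), raw logits, and softmax probabilities for a batch."""

    features: Tensor
    logits: Tensor

    @property
    def probabilities(self) -> np.ndarray:
        return softmax(self.logits.data, axis=-1)


class _ResBlock(nn.Module):
    def __init__(self, channels: int, rng: np.random.Generator):
        self.conv1 = nn.Conv1d(channels, channels, 3, rng, padding=1)
        self.conv2 = nn.Conv1d(channels, channels, 3, rng, padding=1)

    def __call__(self, x: Tensor) -> Tensor:
        return nn.relu(self.conv2(nn.relu(self.conv1(x))) + x)


class Backbone(nn.Module):
    """window batch → (features, logits); see module docstring."""

    def __init__(self, cfg: BackboneConfig, seed: int):
        cfg.validate()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        arch = _PRESETS[cfg.preset]
        stem_c = arch["stem"]
        if cfg.input_layout == "4d":
            # shared 3-channel stem per sensor; concatenation restores stem_c
            if stem_c % 4 != 0:
                raise ValueError("stem width must be divisible by 4 for the 4d layout")
            self.stem = nn.Conv1d(3, stem_c // 4, 5, rng, stride=2, padding=2)
        else:
            self.stem = nn.Conv1d(12, stem_c, 5, rng, stride=2, padding=2)
        self.downsamples: list[nn.Module] = []
        self.blocks: list[nn.Module] = []
        c_prev = stem_c
        for c_out, n_blocks in arch["stages"]:
            self.downsamples.append(nn.Conv1d(c_prev, c_out, 3, rng, stride=2, padding=1))
            self.blocks.append([_ResBlock(c_out, rng) for _ in range(n_blocks)])
            c_prev = c_out
        self.proj = nn.Linear(c_prev, cfg.feature_dim, rng)
        self.head = nn.Linear(cfg.feature_dim, cfg.n_classes, rng)

    def parameters(self) -> list[Tensor]:
        params = self.stem.parameters()
        for ds, blks in zip(self.downsamples, self.blocks):
            params.extend(ds.parameters())
            for b in blks:
                params.extend(b.parameters())
        params.extend(self.proj.parameters())
        params.extend(self.head.parameters())
        return params

    def _check_layout(self, batch: np.ndarray) -> None:
        if self.cfg.input_layout == "4d":
            if batch.ndim != 4 or batch.shape[2:] != (4, 3):
                raise ValueError(f"4d layout expects (n, T, 4, 3), got {batch.shape}")
        else:
            if batch.ndim != 3 or batch.shape[2] != 12:
                raise ValueError(f"1d layout expects (n, T, 12), got {batch.shape}")

    def forward(self, batch: np.ndarray) -> ModelOutput:
        batch = np.asarray(batch, dtype=np.float64)
        self._check_layout(batch)
        x = Tensor(batch)
        if self.cfg.input_layout == "4d":
            b, t = batch.shape[0], batch.shape[1]
            # (B, T, 4, 3) -> (B*4, T, 3): shared stem over sensor groups
            x = x.transpose((0, 2, 1, 3)).reshape(b * 4, t, 3)
            h = nn.relu(self.stem(x))
            tp = h.shape[1]
            # concat sensor feature maps along channels
            h = h.reshape(b, 4, tp, h.shape[2]).transpose((0, 2, 1, 3)).reshape(b, tp, -1)
        else:
            h = nn.relu(self.stem(x))
        for ds, blks in zip(self.downsamples, self.blocks):
            h = nn.relu(ds(h))
            for blk in blks:
                h = blk(h)
        pooled = h.mean(axis=1)  # global average pool over time
        features = nn.relu(self.proj(pooled))
        logits = self.head(features)
        return ModelOutput(features=features, logits=logits)

    __call__ = forward

    def predict(self, batch: np.ndarray) -> np.ndarray:
        """Hard class predictions (argmax; ties break to the lowest index)."""
        return np.argmax(self.forward(batch).logits.data, axis=-1)


def build_model(cfg: BackboneConfig, seed: int) -> Backbone:
    """Fresh backbone with deterministic initialization given ``seed``."""
    return Backbone(cfg, seed)


def forward(model: Backbone, batch: np.ndarray) -> ModelOutput:
    return model.forward(batch)


def save_checkpoint(path: str | Path, model: Backbone, extra: dict | None = None) -> None:
    """Parameters + config (+ JSON-serializable extras) in one .npz archive."""
    arrays = {f"param_{i}": p for i, p in enumerate(model.get_state())}
    meta = {"config": dataclasses.asdict(model.cfg), "extra": extra or {}}
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path, seed: int = 0) -> tuple[Backbone, dict]:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["meta_json"]).decode())
        n = len([k for k in archive.files if k.startswith("param_")])
        state = [archive[f"param_{i}"] for i in range(n)]
    model = Backbone(BackboneConfig(**meta["config"]), seed)
    model.set_state(state)
    return model, meta["extra"]
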