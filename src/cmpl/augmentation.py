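"""Label-preserving window augmentations for consistency training.

Weak augmentation (sign flip with some probability, then Gaussian jitter)
perturbs the window mildly and operates on the flat (T, 12) layout.  Strong
augmentation restructures it — a shared random permutation of the (x, y, z)
axes and/or temporal reversal — and operates on the 4D (T, 4, 3) layout
where the axis grouping is explicit.  All transforms are deterministic given
their seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "AugmentationConfig",
    "flip",
    "jitter",
    "time_inverse",
    "dimension_shuffle",
    "weak_augment",
    "strong_augment",
    "weak_augment_batch",
    "strong_augment_batch",
]


@dataclasses.dataclass(frozen=True)
class AugmentationConfig:
    jitter_sd: float = 0.05
    flip_probability: float = 0.0
    strong_ops: tuple[str, ...] = ("dimension_shuffle", "time_inverse")
    per_sensor_shuffle: bool = False

    def validate(self) -> None:
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if not 0.0 <= self.flip_probability <= 1.0:
            raise ValueError("flip_probability must be in [0, 1]")
        unknown = set(self.strong_ops) - {"dimension_shuffle", "time_inverse"}
        if unknown:
            raise ValueError(f"unknown strong ops: {sorted(unknown)}")


def flip(window: np.ndarray) -> np.ndarray:
    """Sign-flip every channel (mirrored motion). An involution."""
    return -np.asarray(window)


def jitter(window: np.ndarray, sd: float, seed: int) -> np.ndarray:
    """Add i.i.d. Gaussian noise with standard deviation ``sd``."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    window = np.asarray(window, dtype=np.float64)
    if sd == 0:
        return window.copy()
    rng = np.random.default_rng(seed)
    return window + rng.normal(0.0, sd, size=window.shape)


def time_inverse(window: np.ndarray) -> np.ndarray:
    """Reverse temporal order (first axis); channels untouched."""
    return np.asarray(window)[::-1].copy()


def dimension_shuffle(window4d: np.ndarray, seed: int, per_sensor: bool = False) -> np.ndarray:
    """Permute the 3 axis positions of a (T, 4, 3) window.

    One random permutation is shared across all time steps and (by default)
    all sensors; ``per_sensor=True`` draws an independent permutation per
    sensor group.
    """
    window4d = np.asarray(window4d)
    if window4d.ndim != 3 or window4d.shape[1:] != (4, 3):
        raise ValueError(f"expected a (T, 4, 3) window, got {window4d.shape}")
    rng = np.random.default_rng(seed)
    if per_sensor:
        out = np.empty_like(window4d)
        for s in range(4):
            out[:, s, :] = window4d[:, s, rng.permutation(3)]
        return out
    return window4d[:, :, rng.permutation(3)].copy()


def weak_augment(window: np.ndarray, cfg: AugmentationConfig, seed: int) -> np.ndarray:
    """Flip with ``flip_probability``, then jitter. Flat (T, 12) layout."""
    cfg.validate()
    rng = np.random.default_rng(seed)
    out = np.asarray(window, dtype=np.float64)
    if rng.random() < cfg.flip_probability:
        out = flip(out)
    if cfg.jitter_sd > 0:
        out = out + rng.normal(0.0, cfg.jitter_sd, size=out.shape)
    return np.array(out)


def strong_augment(window4d: np.ndarray, cfg: AugmentationConfig, seed: int) -> np.ndarray:
    """Configured strong ops in fixed order (dimension_shuffle, time_inverse).

    Requires at least one enabled op — a strong view must actually transform.
    """
    cfg.validate()
    if not cfg.strong_ops:
        raise ValueError("strong_ops must not be empty")
    out = np.asarray(window4d, dtype=np.float64)
    if "dimension_shuffle" in cfg.strong_ops:
        out = dimension_shuffle(out, seed, per_sensor=cfg.per_sensor_shuffle)
    if "time_inverse" in cfg.strong_ops:
        out = time_inverse(out)
    return out


def weak_augment_batch(batch: np.ndarray, cfg: AugmentationConfig, seed: int) -> np.ndarray:
    """Vectorized weak augmentation of a (n, T, 12) batch.

    Each window gets an independent flip decision and jitter field, all
    derived from one seed.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    n = batch.shape[0]
    signs = np.where(rng.random(n) < cfg.flip_probability, -1.0, 1.0)
    out = batch * signs[:, None, None]
    if cfg.jitter_sd > 0:
        out = out + rng.normal(0.0, cfg.jitter_sd, size=batch.shape)
    return out


def strong_augment_batch(batch4d: np.ndarray, cfg: AugmentationConfig, seed: int) -> np.ndarray:
    """Strong augmentation of a (n, T, 4, 3) batch, one permutation per window."""
    cfg.validate()
    if not cfg.strong_ops:
        raise ValueError("strong_ops must not be empty")
    rng = np.random.default_rng(seed)
    out = np.asarray(batch4d, dtype=np.float64).copy()
    if "dimension_shuffle" in cfg.strong_ops:
        for i in range(out.shape[0]):
            if cfg.per_sensor_shuffle:
                for s in range(4):
                    out[i, :, s, :] = out[i, :, s, :][:, rng.permutation(3)]
            else:
                out[i] = out[i][:, :, rng.permutation(3)]
    if "time_inverse" in cfg.strong_ops:
        out = out[:, ::-1].copy()
    return out
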