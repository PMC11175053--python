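"""Window preprocessing: missing-value removal, z-scoring, 4D reshaping.

Windows containing any missing sample are dropped outright rather than
interpolated — with a small labeled pool, label fidelity beats data volume.
Normalization statistics are per channel, fitted on the labeled training
pool only and reused unchanged everywhere else.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np

from .synthetic_data import N_CHANNELS, WindowSet

__all__ = [
    "NormalizationStats",
    "drop_missing_windows",
    "fit_normalizer",
    "apply_normalizer",
    "invert_normalizer",
    "reshape_4d",
    "flatten_4d",
    "slice_windows",
    "RAW_RANGES",
]

log = logging.getLogger(__name__)

#: plausible raw sensor ranges (validation bounds for real-data ingestion)
RAW_RANGES = {"gyro": (-16.4, 16.4), "acc": (-2048.0, 2048.0), "mag": (-2000.0, 2000.0), "rot": (-2000.0, 2000.0)}

_EPS = 1e-8


@dataclasses.dataclass(frozen=True)
class NormalizationStats:
    """Per-channel mean and standard deviation (12-vectors)."""

    mean: np.ndarray
    sd: np.ndarray

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"mean": self.mean.tolist(), "sd": self.sd.tolist()})
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationStats":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["mean"], dtype=np.float64), np.asarray(d["sd"], dtype=np.float64))


def drop_missing_windows(windows: WindowSet) -> WindowSet:
    """Remove every window containing at least one missing (NaN) sample."""
    mask = ~windows.has_missing
    dropped = int((~mask).sum())
    if dropped:
        log.info("dropped %d/%d windows with missing values", dropped, len(windows))
    return windows.subset(mask)


def fit_normalizer(windows: WindowSet) -> NormalizationStats:
    """Per-channel mean/sd over all time steps of all windows.

    Zero-variance channels get sd clamped to a small epsilon so that
    normalization never divides by zero (logged).
    """
    if len(windows) == 0:
        raise ValueError("cannot fit normalizer on an empty window set")
    if np.isnan(windows.values).any():
        raise ValueError("fit_normalizer requires missing values to be dropped first")
    flat = windows.values.reshape(-1, N_CHANNELS)
    mean = flat.mean(axis=0)
    sd = flat.std(axis=0)
    degenerate = sd < _EPS
    if degenerate.any():
        log.warning("clamping sd to %g on %d zero-variance channels", _EPS, int(degenerate.sum()))
        sd = np.where(degenerate, _EPS, sd)
    return NormalizationStats(mean, sd)


def apply_normalizer(windows: WindowSet, stats: NormalizationStats) -> WindowSet:
    """(value − mean) / sd per channel; labels pass through."""
    return WindowSet((windows.values - stats.mean) / stats.sd, windows.labels)


def invert_normalizer(windows: WindowSet, stats: NormalizationStats) -> WindowSet:
    """Undo :func:`apply_normalizer`."""
    return WindowSet(windows.values * stats.sd + stats.mean, windows.labels)


def reshape_4d(values: np.ndarray) -> np.ndarray:
    """(…, T, 12) → (…, T, 4, 3): group channels into sensors × axes.

    ``out[..., t, s, a] = in[..., t, 3 s + a]`` — a pure view-preserving
    reshape, bijective with :func:`flatten_4d`.
    """
    values = np.asarray(values)
    if values.shape[-1] != N_CHANNELS:
        raise ValueError(f"last axis must be {N_CHANNELS}, got {values.shape}")
    return values.reshape(*values.shape[:-1], 4, 3)


def flatten_4d(values4d: np.ndarray) -> np.ndarray:
    """(…, T, 4, 3) → (…, T, 12): inverse of :func:`reshape_4d`."""
    values4d = np.asarray(values4d)
    if values4d.shape[-2:] != (4, 3):
        raise ValueError(f"last axes must be (4, 3), got {values4d.shape}")
    return values4d.reshape(*values4d.shape[:-2], N_CHANNELS)


def slice_windows(stream: np.ndarray, window_len: int, stride: int | None = None) -> np.ndarray:
    """Cut a (T, 12) stream into (n, window_len, 12) windows.

    Windows start at offsets 0, stride, 2·stride, …; a trailing partial
    window is discarded.  Default stride is ``window_len`` (non-overlapping).
    """
    stream = np.asarray(stream)
    if stride is None:
        stride = window_len
    if window_len < 1 or stride < 1:
        raise ValueError("window_len and stride must be >= 1")
    t = stream.shape[0]
    if t < window_len:
        log.info("stream of %d samples shorter than window_len=%d; no windows", t, window_len)
        return np.empty((0, window_len) + stream.shape[1:])
    n = (t - window_len) // stride + 1
    return np.stack([stream[i * stride : i * stride + window_len] for i in range(n)])
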