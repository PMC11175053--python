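"""Synthetic wearable-sensor streams for five dog behaviors.

Real collar recordings (accelerometer, gyroscope, magnetometer, rotation
angles at 50 Hz) are private, so this module fabricates statistically similar
data: each behavior class is a harmonic motion motif with class-specific
amplitudes, fundamental frequency and baseline posture offsets; the unlabeled
pool is contaminated with "inactive" windows (low-variance noise belonging to
no class) and with contiguous missing-value gaps mimicking Bluetooth
transmission loss.

Channel order is fixed: gyro x/y/z, acc x/y/z, mag x/y/z, rotation
roll/pitch/yaw.  Windows are 2 s long (100 samples at 50 Hz).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "BehaviorMotif",
    "StreamSpec",
    "SensorWindow",
    "WindowSet",
    "SyntheticDataset",
    "BEHAVIOR_NAMES",
    "CHANNEL_NAMES",
    "INACTIVE_LABEL",
    "UNLABELED",
    "default_motifs",
    "generate_window",
    "generate_inactive_window",
    "make_dataset",
    "write_csv",
    "read_csv",
    "write_manifest",
]

BEHAVIOR_NAMES = ("stand", "walk", "sit", "lying", "eat")
SENSOR_NAMES = ("gyro", "acc", "mag", "rot")
CHANNEL_NAMES = (
    "gyro_x", "gyro_y", "gyro_z",
    "acc_x", "acc_y", "acc_z",
    "mag_x", "mag_y", "mag_z",
    "rot_roll", "rot_pitch", "rot_yaw",
)
N_CHANNELS = 12
N_CLASSES = 5
#: label value marking an inactive (class-less) window
INACTIVE_LABEL = 5
#: label value for unlabeled windows
UNLABELED = -1


class ConfigurationError(ValueError):
    """Raised for invalid motifs or stream specifications."""


@dataclasses.dataclass(frozen=True)
class BehaviorMotif:
    """Harmonic motion signature of one behavior class.

    ``amplitude`` holds one value per sensor group (gyro, acc, mag, rot);
    within a group the three axes share the amplitude but get independent
    random phases.  Harmonic k of the fundamental is scaled by 1/k, so the
    fundamental dominates the spectrum.
    """

    class_id: int
    amplitude: tuple[float, float, float, float]
    frequency: float  # Hz, fundamental
    harmonics: int = 1
    noise_sd: float = 0.15
    baseline: tuple[float, ...] = (0.0,) * N_CHANNELS
    phase_jitter: float = 0.4  # rad, window-to-window wobble around the class phase pattern

    def validate(self, sample_rate: float = 50.0) -> None:
        if not 0 <= self.class_id < N_CLASSES:
            raise ConfigurationError(f"class_id {self.class_id} outside 0..{N_CLASSES - 1}")
        if len(self.amplitude) != 4 or any(a < 0 for a in self.amplitude):
            raise ConfigurationError("amplitude must be 4 non-negative values")
        if not 0 < self.frequency < sample_rate / 2:
            raise ConfigurationError(
                f"frequency {self.frequency} outside (0, {sample_rate / 2}) Hz"
            )
        if self.harmonics < 1:
            raise ConfigurationError("harmonics must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if len(self.baseline) != N_CHANNELS:
            raise ConfigurationError("baseline must have 12 entries")
        if self.phase_jitter < 0:
            raise ConfigurationError("phase_jitter must be >= 0")


@dataclasses.dataclass(frozen=True)
class StreamSpec:
    """Size and contamination parameters of one synthetic dataset."""

    sample_rate: float = 50.0
    window_len: int = 100
    n_labeled_per_class: int = 40
    n_unlabeled: int = 300
    inactive_fraction: float = 0.3
    missing_rate: float = 0.0
    test_fraction: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        for name in ("inactive_fraction", "missing_rate", "test_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.window_len < 2 or self.sample_rate <= 0:
            raise ConfigurationError("window_len >= 2 and sample_rate > 0 required")

    @property
    def n_test_per_class(self) -> int:
        if self.test_fraction >= 1.0:
            raise ConfigurationError("test_fraction must be < 1")
        return max(1, round(self.n_labeled_per_class * self.test_fraction / (1 - self.test_fraction)))


@dataclasses.dataclass
class SensorWindow:
    """One 2-s window: (window_len, 12) values plus an optional label.

    ``label`` is an int in 0..4 for behaviors, ``INACTIVE_LABEL`` (5) for
    inactive windows, or ``UNLABELED`` (-1).  Missing samples are NaN.
    """

    values: np.ndarray
    label: int = UNLABELED

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())


class WindowSet:
    """A stack of equally sized windows: values (n, T, 12), labels (n,)."""

    def __init__(self, values: np.ndarray, labels: np.ndarray):
        values = np.asarray(values, dtype=np.float64)
        labels = np.asarray(labels, dtype=np.int64)
        if values.ndim != 3 or values.shape[2] != N_CHANNELS:
            raise ValueError(f"values must be (n, T, {N_CHANNELS}), got {values.shape}")
        if labels.shape != (values.shape[0],):
            raise ValueError("labels length mismatch")
        self.values = values
        self.labels = labels

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def has_missing(self) -> np.ndarray:
        return np.isnan(self.values).any(axis=(1, 2))

    def subset(self, index) -> "WindowSet":
        return WindowSet(self.values[index], self.labels[index])

    def windows(self) -> list[SensorWindow]:
        return [SensorWindow(v.copy(), int(l)) for v, l in zip(self.values, self.labels)]

    @classmethod
    def from_windows(cls, windows: list[SensorWindow]) -> "WindowSet":
        if not windows:
            return cls(np.empty((0, 100, N_CHANNELS)), np.empty(0, dtype=np.int64))
        return cls(
            np.stack([w.values for w in windows]),
            np.array([w.label for w in windows], dtype=np.int64),
        )


class SyntheticDataset(NamedTuple):
    """Output of :func:`make_dataset`.

    ``inactive_mask`` and ``unlabeled_truth`` describe the unlabeled pool and
    exist for evaluation only; training code never reads them.
    """

    labeled: WindowSet
    unlabeled: WindowSet
    test: WindowSet
    inactive_mask: np.ndarray
    unlabeled_truth: np.ndarray


def default_motifs(noise_sd: float = 0.15) -> list[BehaviorMotif]:
    """The five stock behavior signatures.

    stand: slow low-amplitude drift; walk: strong periodic gyro/acc; sit:
    modest low-frequency motion with a posture offset; lying: near-static
    with distinct magnetometer/rotation offsets; eat: mid-frequency
    acc-dominated bursts.
    """
    z = (0.0,) * 3
    return [
        BehaviorMotif(0, (0.15, 0.10, 0.05, 0.10), 0.3, 1, noise_sd),
        BehaviorMotif(1, (1.20, 1.00, 0.30, 0.50), 2.5, 3, noise_sd),
        BehaviorMotif(
            2, (0.30, 0.25, 0.10, 0.30), 0.8, 2, noise_sd,
            baseline=z + z + (0.3, -0.3, 0.1) + (0.6, -0.4, 0.2),
        ),
        BehaviorMotif(
            3, (0.10, 0.08, 0.05, 0.08), 0.4, 1, noise_sd,
            baseline=z + z + (-1.2, 0.9, -0.5) + (-1.0, 0.7, -0.3),
        ),
        BehaviorMotif(
            4, (0.50, 1.10, 0.20, 0.40), 4.5, 3, noise_sd,
            baseline=z + (0.3, 0.0, -0.2) + z + z,
        ),
    ]


def generate_window(
    motif: BehaviorMotif,
    seed: int,
    sample_rate: float = 50.0,
    window_len: int = 100,
) -> SensorWindow:
    """One labeled window drawn from a behavior motif.

    Each channel is the motif baseline plus a 1/k-weighted harmonic series at
    the fundamental frequency plus white Gaussian noise.  The inter-channel
    phase pattern is a fixed property of the class (repetitive behaviors keep
    their limb/head coordination), derived deterministically from
    ``class_id``; each window wobbles around it by ``phase_jitter`` radians.
    Deterministic given ``(motif, seed)``.
    """
    motif.validate(sample_rate)
    rng = np.random.default_rng(seed)
    t = np.arange(window_len) / sample_rate
    base_phases = np.random.default_rng(7919 * (motif.class_id + 1)).uniform(
        0.0, 2.0 * np.pi, size=(N_CHANNELS, motif.harmonics)
    )
    phases = base_phases + rng.normal(0.0, motif.phase_jitter, size=(N_CHANNELS, motif.harmonics))
    noise = rng.normal(0.0, motif.noise_sd, size=(window_len, N_CHANNELS)) if motif.noise_sd > 0 else 0.0
    values = np.empty((window_len, N_CHANNELS))
    for c in range(N_CHANNELS):
        amp = motif.amplitude[c // 3]
        sig = motif.baseline[c]
        for k in range(1, motif.harmonics + 1):
            sig = sig + (amp / k) * np.sin(2.0 * np.pi * motif.frequency * k * t + phases[c, k - 1])
        values[:, c] = sig
    values += noise
    return SensorWindow(values, motif.class_id)


def generate_inactive_window(
    noise_sd: float,
    seed: int,
    window_len: int = 100,
    offset_sd: float = 0.6,
    posture: "np.ndarray | None" = None,
    posture_sd: float = 0.2,
) -> SensorWindow:
    """A class-less low-activity window: static offset plus white noise.

    An idle animal holds a realistic resting posture, so by default the
    dataset builder passes ``posture`` — the baseline of a randomly chosen
    behavior class — and the window sits near it (per-channel deviation
    ``posture_sd``) with no motion on top.  Without a posture the offset is
    drawn freely with spread ``offset_sd``, comparable to the class
    baselines.  Either way the within-window variance stays far below any
    behavior's; what makes the window "inactive" is the absence of motion,
    not an exotic position in sensor space.
    """
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    if posture is None:
        offset = rng.normal(0.0, offset_sd, size=N_CHANNELS)
    else:
        offset = np.asarray(posture, dtype=np.float64) + rng.normal(0.0, posture_sd, size=N_CHANNELS)
    values = np.tile(offset, (window_len, 1))
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=(window_len, N_CHANNELS))
    return SensorWindow(values, INACTIVE_LABEL)


def _inject_missing(values: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    """Contiguous all-channel gaps (NaN), geometric length (mean 5 samples).

    ``rate`` is the probability that a window is hit at all, mimicking the
    bursty nature of Bluetooth dropouts.
    """
    n, t, _ = values.shape
    for i in range(n):
        if rng.random() < rate:
            gap = min(int(rng.geometric(1.0 / 5.0)), t)
            start = int(rng.integers(0, t - gap + 1))
            values[i, start : start + gap, :] = np.nan


def make_dataset(spec: StreamSpec, motifs: list[BehaviorMotif] | None = None) -> SyntheticDataset:
    """Build labeled / unlabeled / test pools plus evaluation-only truth.

    The labeled and test pools are stratified over the five classes
    (80/20 by default).  The unlabeled pool mixes behavior windows (uniform
    classes) with ``inactive_fraction`` inactive windows, shuffled; its
    labels are all ``UNLABELED``.  Missing-value gaps are injected into the
    labeled and unlabeled pools (never the test set).
    """
    spec.validate()
    if motifs is None:
        motifs = default_motifs()
    if len(motifs) != N_CLASSES or sorted(m.class_id for m in motifs) != list(range(N_CLASSES)):
        raise ConfigurationError("need exactly 5 motifs, one per class 0..4")
    by_class = {m.class_id: m for m in motifs}
    rng = np.random.default_rng(spec.seed)

    def draw(motif: BehaviorMotif) -> SensorWindow:
        return generate_window(
            motif, int(rng.integers(2**31)), spec.sample_rate, spec.window_len
        )

    labeled = [draw(by_class[c]) for c in range(N_CLASSES) for _ in range(spec.n_labeled_per_class)]
    test = [draw(by_class[c]) for c in range(N_CLASSES) for _ in range(spec.n_test_per_class)]

    n_inactive = round(spec.inactive_fraction * spec.n_unlabeled)
    n_active = spec.n_unlabeled - n_inactive
    truth = np.concatenate(
        [
            rng.integers(0, N_CLASSES, size=n_active),
            np.full(n_inactive, INACTIVE_LABEL, dtype=np.int64),
        ]
    )
    unlabeled = [
        draw(by_class[int(c)])
        if c != INACTIVE_LABEL
        else generate_inactive_window(
            0.05,
            int(rng.integers(2**31)),
            spec.window_len,
            posture=np.asarray(by_class[int(rng.integers(N_CLASSES))].baseline),
        )
        for c in truth
    ]
    perm = rng.permutation(spec.n_unlabeled)
    truth = truth[perm]
    unlabeled = [unlabeled[i] for i in perm]

    labeled_set = WindowSet.from_windows(labeled)
    test_set = WindowSet.from_windows(test)
    unlabeled_set = WindowSet(
        np.stack([w.values for w in unlabeled]) if unlabeled else np.empty((0, spec.window_len, N_CHANNELS)),
        np.full(len(unlabeled), UNLABELED, dtype=np.int64),
    )
    _inject_missing(labeled_set.values, spec.missing_rate, rng)
    _inject_missing(unlabeled_set.values, spec.missing_rate, rng)
    return SyntheticDataset(
        labeled_set, unlabeled_set, test_set, truth == INACTIVE_LABEL, truth
    )


class CSVFormatError(ValueError):
    """Malformed sensor CSV (wrong columns or unparseable row)."""


_LABEL_TO_FIELD = {UNLABELED: "", INACTIVE_LABEL: "inactive"}
_FIELD_TO_LABEL = {"": UNLABELED, "inactive": INACTIVE_LABEL}


def write_csv(windows: WindowSet, path: str | Path, sample_rate: float = 50.0) -> None:
    """Write windows as one contiguous CSV stream.

    Columns: ``time`` (s), the 12 sensor channels, ``label``.  Missing
    samples become empty fields; unlabeled windows get an empty label field
    and inactive windows the literal ``inactive``.
    """
    n, t, _ = windows.values.shape
    flat = windows.values.reshape(n * t, N_CHANNELS)
    df = pd.DataFrame(flat, columns=list(CHANNEL_NAMES))
    df.insert(0, "time", np.arange(n * t) / sample_rate)
    labels = np.repeat(windows.labels, t)
    df["label"] = [
        _LABEL_TO_FIELD.get(int(l), str(int(l))) for l in labels
    ]
    df.to_csv(path, index=False, float_format="%.10g")


def read_csv(path: str | Path, window_len: int = 100) -> WindowSet:
    """Read a stream written by :func:`write_csv` back into windows.

    Raises :class:`CSVFormatError` (naming the offending line where pandas
    reports one) for wrong column sets, ragged rows, or non-numeric values.
    """
    try:
        df = pd.read_csv(path, dtype={"label": "string"})
    except pd.errors.ParserError as exc:
        raise CSVFormatError(f"malformed CSV: {exc}") from exc
    expected = ["time", *CHANNEL_NAMES, "label"]
    if list(df.columns) != expected:
        raise CSVFormatError(
            f"expected columns {expected}, got {list(df.columns)} (line 1)"
        )
    n_rows = len(df)
    if n_rows == 0 or n_rows % window_len != 0:
        raise CSVFormatError(f"row count {n_rows} is not a multiple of window_len={window_len}")
    try:
        values = df[list(CHANNEL_NAMES)].to_numpy(dtype=np.float64)
    except (TypeError, ValueError) as exc:
        raise CSVFormatError(f"non-numeric sensor value: {exc}") from exc
    label_field = df["label"].fillna("").to_numpy()
    labels = np.empty(n_rows // window_len, dtype=np.int64)
    for w in range(labels.size):
        block = label_field[w * window_len : (w + 1) * window_len]
        uniq = set(block.tolist())
        if len(uniq) != 1:
            raise CSVFormatError(
                f"inconsistent labels inside window {w} (lines {w * window_len + 2}.."
                f"{(w + 1) * window_len + 1})"
            )
        field = uniq.pop()
        if field in _FIELD_TO_LABEL:
            labels[w] = _FIELD_TO_LABEL[field]
        else:
            try:
                labels[w] = int(field)
            except ValueError as exc:
                raise CSVFormatError(f"bad label {field!r} in window {w}") from exc
    return WindowSet(values.reshape(-1, window_len, N_CHANNELS), labels)


def write_manifest(dataset: SyntheticDataset, spec: StreamSpec, path: str | Path) -> None:
    """JSON sidecar: per-class counts, contamination, and the spec echo."""
    counts = {
        BEHAVIOR_NAMES[c]: int((dataset.labeled.labels == c).sum()) for c in range(N_CLASSES)
    }
    manifest = {
        "labeled_per_class": counts,
        "n_labeled": len(dataset.labeled),
        "n_unlabeled": len(dataset.unlabeled),
        "n_test": len(dataset.test),
        "n_inactive": int(dataset.inactive_mask.sum()),
        "spec": dataclasses.asdict(spec),
    }
    Path(path).write_text(json.dumps(manifest, indent=2))
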