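"""Metrics and the desk-scale benchmark harness.

Behavior metrics cover the five behavior classes only; predictions of the
inactive class on behavior-labeled test data count as plain errors in
accuracy/F1.  Noise detection quality (the inactive flagging itself) is
reported separately as precision/recall against the ground-truth mask of the
synthetic unlabeled pool.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
from sklearn.metrics import accuracy_score, confusion_matrix, f1_score, recall_score

from .augmentation import AugmentationConfig
from .model import BackboneConfig
from .preprocessing import apply_normalizer, drop_missing_windows, fit_normalizer
from .synthetic_data import BEHAVIOR_NAMES, N_CLASSES, UNLABELED, SyntheticDataset, WindowSet
from .training import TrainConfig, TrainResult, detect_inactive, train

__all__ = [
    "Metrics",
    "BenchmarkCell",
    "BenchmarkGrid",
    "METHODS",
    "compute_metrics",
    "run_benchmark",
    "pseudo_label_accuracy_curve",
    "noise_detection_report",
]

log = logging.getLogger(__name__)

BEHAVIOR_CLASSES = list(range(N_CLASSES))

#: method name → (mpl_enabled, uda_enabled, cleaning_enabled)
METHODS: dict[str, tuple[bool, bool, bool]] = {
    "supervised": (False, False, False),
    "mpl": (True, False, False),
    "mpl+uda": (True, True, False),
    "cleaned": (True, True, True),
}


@dataclasses.dataclass
class Metrics:
    """Accuracy / macro F1 / macro recall in percent, plus the confusion matrix.

    ``confusion`` is 5×5, rows = actual class, columns = predicted class,
    each row normalized to sum to 1 over the behavior columns (rows with no
    behavior prediction stay zero).
    """

    accuracy: float
    macro_f1: float
    macro_recall: float
    test_loss: float | None
    confusion: np.ndarray
    support: np.ndarray


def compute_metrics(
    predictions: np.ndarray, labels: np.ndarray, test_loss: float | None = None
) -> Metrics:
    """Score hard predictions against behavior labels (0..4)."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have the same length")
    if predictions.size == 0:
        raise ValueError("cannot compute metrics on empty inputs")
    acc = accuracy_score(labels, predictions) * 100.0
    f1 = f1_score(labels, predictions, labels=BEHAVIOR_CLASSES, average="macro", zero_division=0) * 100.0
    rec = recall_score(labels, predictions, labels=BEHAVIOR_CLASSES, average="macro", zero_division=0) * 100.0
    cm = confusion_matrix(labels, predictions, labels=BEHAVIOR_CLASSES).astype(float)
    row_sums = cm.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        cm_norm = np.where(row_sums > 0, cm / np.where(row_sums == 0, 1, row_sums), 0.0)
    support = np.array([(labels == c).sum() for c in BEHAVIOR_CLASSES])
    return Metrics(acc, f1, rec, test_loss, cm_norm, support)


@dataclasses.dataclass
class BenchmarkCell:
    method: str
    label_ratio: float
    seed: int
    metrics: Metrics | None = None
    noise_precision: float | None = None
    noise_recall: float | None = None
    error: str | None = None


@dataclasses.dataclass
class BenchmarkGrid:
    protocol: str
    cells: list[BenchmarkCell]

    def mean_accuracy(self, method: str, label_ratio: float) -> float:
        accs = [
            c.metrics.accuracy
            for c in self.cells
            if c.method == method and c.label_ratio == label_ratio and c.metrics is not None
        ]
        if not accs:
            raise ValueError(f"no successful cells for {method} @ {label_ratio}")
        return float(np.mean(accs))

    def to_rows(self) -> list[dict]:
        rows = []
        for c in self.cells:
            rows.append(
                {
                    "method": c.method,
                    "label_ratio": c.label_ratio,
                    "seed": c.seed,
                    "accuracy": c.metrics.accuracy if c.metrics else None,
                    "macro_f1": c.metrics.macro_f1 if c.metrics else None,
                    "test_loss": c.metrics.test_loss if c.metrics else None,
                    "noise_precision": c.noise_precision,
                    "noise_recall": c.noise_recall,
                    "error": c.error,
                }
            )
        return rows

    def to_markdown(self) -> str:
        lines = [
            f"# Benchmark ({self.protocol} protocol)",
            "",
            "| method | label ratio | mean ACC (%) | mean F1 (%) | seeds |",
            "|---|---|---|---|---|",
        ]
        combos = sorted({(c.method, c.label_ratio) for c in self.cells})
        for method, ratio in combos:
            ok = [c for c in self.cells if c.method == method and c.label_ratio == ratio and c.metrics]
            if not ok:
                lines.append(f"| {method} | {ratio:.0%} | failed | failed | 0 |")
                continue
            acc = np.mean([c.metrics.accuracy for c in ok])
            f1 = np.mean([c.metrics.macro_f1 for c in ok])
            lines.append(f"| {method} | {ratio:.0%} | {acc:.2f} | {f1:.2f} | {len(ok)} |")
        return "\n".join(lines) + "\n"


def _stratified_subset(pool: WindowSet, ratio: float, rng: np.random.Generator):
    """Split a labeled pool per class into (kept, rest) at ``ratio``."""
    keep_idx, rest_idx = [], []
    for c in np.unique(pool.labels):
        idx = np.flatnonzero(pool.labels == c)
        idx = rng.permutation(idx)
        k = max(1, round(ratio * idx.size))
        keep_idx.append(idx[:k])
        rest_idx.append(idx[k:])
    return np.concatenate(keep_idx), np.concatenate(rest_idx)


def _strip_labels(pool: WindowSet) -> WindowSet:
    return WindowSet(pool.values, np.full(len(pool), UNLABELED, dtype=np.int64))


def run_single(
    dataset: SyntheticDataset,
    method: str,
    label_ratio: float,
    seed: int,
    base_cfg: TrainConfig,
    model_cfg: BackboneConfig | None = None,
    aug_cfg: AugmentationConfig | None = None,
    protocol: str = "contaminated",
) -> BenchmarkCell:
    """Train and score one benchmark cell.

    ``relabel`` protocol: part of the labeled pool is hidden and used as the
    unlabeled pool (no contamination).  ``contaminated`` protocol: the true
    unlabeled pool, inactive windows and all, is used.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(METHODS)}")
    if protocol not in ("relabel", "contaminated"):
        raise ValueError(f"unknown protocol {protocol!r}")
    mpl_on, uda_on, cleaning_on = METHODS[method]
    rng = np.random.default_rng(seed)
    labeled_full = drop_missing_windows(dataset.labeled)
    keep, rest = _stratified_subset(labeled_full, label_ratio, rng)
    labeled = labeled_full.subset(keep)
    if protocol == "relabel":
        unlabeled = _strip_labels(labeled_full.subset(rest)) if rest.size else _strip_labels(labeled)
        inactive_mask = None
    else:
        unlabeled = drop_missing_windows(dataset.unlabeled)
        inactive_mask = dataset.inactive_mask[~dataset.unlabeled.has_missing]
    stats = fit_normalizer(labeled)
    labeled = apply_normalizer(labeled, stats)
    unlabeled = apply_normalizer(unlabeled, stats)
    test = apply_normalizer(dataset.test, stats)
    cfg = dataclasses.replace(
        base_cfg,
        mpl_enabled=mpl_on,
        uda_enabled=uda_on,
        cleaning_enabled=cleaning_on,
        seed=int(rng.integers(2**31)),
    )
    result = train(labeled, unlabeled, test, cfg, model_cfg, aug_cfg)
    cell = BenchmarkCell(method, label_ratio, seed, metrics=result.metrics_history[-1][1])
    if cleaning_on and inactive_mask is not None and inactive_mask.any():
        prec, rec = noise_detection_report(result, unlabeled, inactive_mask)
        cell.noise_precision, cell.noise_recall = prec, rec
    return cell


def run_benchmark(
    dataset: SyntheticDataset,
    methods: list[str],
    label_ratios: list[float],
    seeds: list[int],
    base_cfg: TrainConfig,
    model_cfg: BackboneConfig | None = None,
    aug_cfg: AugmentationConfig | None = None,
    protocol: str = "contaminated",
    out_dir: str | Path | None = None,
) -> BenchmarkGrid:
    """Full method × label-ratio × seed grid; failed cells are recorded, not fatal."""
    cells: list[BenchmarkCell] = []
    for method in methods:
        for ratio in label_ratios:
            for seed in seeds:
                try:
                    cell = run_single(
                        dataset, method, ratio, seed, base_cfg, model_cfg, aug_cfg, protocol
                    )
                except Exception as exc:  # noqa: BLE001 — grid must continue
                    log.exception("cell failed: %s @ %s seed %d", method, ratio, seed)
                    cell = BenchmarkCell(method, ratio, seed, error=str(exc))
                cells.append(cell)
    grid = BenchmarkGrid(protocol, cells)
    if out_dir is not None:
        _write_report(grid, Path(out_dir))
    return grid


def _write_report(grid: BenchmarkGrid, out_dir: Path) -> None:
    import pandas as pd

    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(grid.to_rows()).to_csv(out_dir / "benchmark.csv", index=False)
    (out_dir / "benchmark.md").write_text(grid.to_markdown())
    for cell in grid.cells:
        if cell.metrics is None:
            continue
        _confusion_figure(
            cell.metrics.confusion,
            out_dir / f"confusion_{cell.method.replace('+', '_')}_{cell.label_ratio:.2f}_s{cell.seed}.png",
            title=f"{cell.method} @ {cell.label_ratio:.0%} (seed {cell.seed})",
        )


def _confusion_figure(confusion: np.ndarray, path: Path, title: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(confusion, vmin=0, vmax=1, cmap="Blues")
    ax.set_xticks(range(N_CLASSES), BEHAVIOR_NAMES, rotation=45)
    ax.set_yticks(range(N_CLASSES), BEHAVIOR_NAMES)
    ax.set_xlabel("predicted")
    ax.set_ylabel("actual")
    ax.set_title(title)
    for i in range(N_CLASSES):
        for j in range(N_CLASSES):
            ax.text(j, i, f"{confusion[i, j]:.2f}", ha="center", va="center", fontsize=8)
    fig.colorbar(im, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def pseudo_label_accuracy_curve(result: TrainResult, unlabeled_truth: np.ndarray) -> np.ndarray:
    """Accuracy of the cleaned pseudo labels per logging interval.

    Behavior windows score correct when the cleaned pseudo label matches the
    true class; inactive windows score correct when flagged as noise.
    """
    if not result.pseudo_log:
        raise ValueError("training run recorded no pseudo-label history")
    unlabeled_truth = np.asarray(unlabeled_truth)
    series = np.empty(len(result.pseudo_log))
    for i, rec in enumerate(result.pseudo_log):
        truth = unlabeled_truth[rec.unlabeled_idx]
        inactive = truth >= N_CLASSES
        correct = np.where(inactive, rec.noise_mask, rec.labels == truth)
        series[i] = float(np.mean(correct))
    return series


def noise_detection_report(
    result: TrainResult, unlabeled: WindowSet, inactive_mask: np.ndarray
) -> tuple[float, float]:
    """Precision and recall of the final flagged set vs the ground truth."""
    flagged, _ = detect_inactive(result.teacher, unlabeled, result.state)
    inactive_mask = np.asarray(inactive_mask, dtype=bool)
    tp = int((flagged & inactive_mask).sum())
    precision = tp / flagged.sum() if flagged.any() else 0.0
    recall = tp / inactive_mask.sum() if inactive_mask.any() else 0.0
    return float(precision), float(recall)
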