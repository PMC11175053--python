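"""The cleaned meta pseudo labels (CMPL) training loop.

Teacher–student meta pseudo labels with two additions on the teacher side:

* a UDA consistency term tying the teacher's predictions on weakly and
  strongly augmented views of the same unlabeled window, plus the usual
  supervised cross entropy on labeled data;
* embedding-space cleaning — a distance loss pulls labeled feature vectors
  toward a running centroid C, every unlabeled window gets a distance score
  S(x) = ||φ(x) − C||², and windows scoring above an adaptive threshold
  T = μ + β·σ are flagged as inactive and either relabeled to the dedicated
  noise class (index 5) or excluded from the student's loss.

μ and σ are exponential moving averages of the labeled-batch score mean and
standard deviation; β is ramped linearly by a scheduler so the cut tightens
relative to σ as the embedding stabilizes.  The student takes one SGD step
per iteration on the cleaned pseudo labels; the scalar feedback
h = CE_labeled(before) − CE_labeled(after) (h > 0 ⇔ the pseudo labels helped)
weights the teacher's MPL term h·CE(ŷ_u, T(x_u)), whose expectation over the
teacher's label distribution equals the exact gradient of the two-step
bilevel objective.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import NamedTuple

import numpy as np

from . import nn
from ._autodiff import Tensor
from .augmentation import AugmentationConfig, strong_augment_batch, weak_augment_batch
from .model import Backbone, BackboneConfig, build_model
from .preprocessing import flatten_4d, reshape_4d
from .synthetic_data import INACTIVE_LABEL, WindowSet

__all__ = [
    "TrainConfig",
    "EmbeddingState",
    "PseudoLabelBatch",
    "LossBreakdown",
    "TrainResult",
    "assemble_batch",
    "pseudo_label",
    "distance_scores",
    "distance_scores_from_features",
    "clean_pseudo_labels",
    "student_step",
    "compute_h",
    "mpl_loss",
    "consistency_loss",
    "uda_loss",
    "distance_loss",
    "update_centroid",
    "update_threshold",
    "beta_schedule",
    "teacher_step",
    "train",
    "desk_preset",
    "detect_inactive",
]

log = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one CMPL run.

    Defaults follow the full-scale protocol (batch 50, 50,000 steps); the
    desk-scale presets used by the benchmark harness are much smaller.
    ``noise_mode`` chooses what happens to flagged windows: ``relabel``
    rewrites their pseudo label to the inactive class, ``exclude`` zeroes
    their weight in the student loss.
    """

    batch_size: int = 50
    total_steps: int = 50_000
    student_lr: float = 0.03
    teacher_lr: float = 0.03
    centroid_lr: float = 0.1
    ema_alpha: float = 0.05
    beta_start: float = 1.0
    beta_end: float = 3.0
    noise_mode: str = "relabel"
    dis_weight: float = 0.05
    clip_norm: float | None = 5.0
    uda_enabled: bool = True
    cleaning_enabled: bool = True
    mpl_enabled: bool = True
    warmup_frac: float = 0.1
    momentum: float = 0.0
    pseudo_view: str = "raw"  # view the teacher labels: "raw" or "weak"
    rewrite_conf_gate: float = 0.95  # skip the class-5 consistency rewrite above this confidence
    eval_ema: float | None = 0.99  # Polyak decay for the evaluation copies; None = raw params
    log_every: int = 50
    eval_every: int = 0  # 0 = final evaluation only
    seed: int = 0

    def validate(self) -> None:
        if self.student_lr < 0 or self.teacher_lr < 0:
            raise ValueError("learning rates must be >= 0")
        if not 0 < self.centroid_lr <= 1:
            raise ValueError("centroid_lr must be in (0, 1]")
        if not 0 < self.ema_alpha <= 1:
            raise ValueError("ema_alpha must be in (0, 1]")
        if self.beta_start < 0 or self.beta_end < self.beta_start:
            raise ValueError("need beta_end >= beta_start >= 0")
        if self.noise_mode not in ("relabel", "exclude"):
            raise ValueError(f"unknown noise_mode {self.noise_mode!r}")
        if self.pseudo_view not in ("weak", "raw"):
            raise ValueError(f"unknown pseudo_view {self.pseudo_view!r}")
        if not 0 <= self.warmup_frac < 1:
            raise ValueError("warmup_frac must be in [0, 1)")
        if self.dis_weight < 0:
            raise ValueError("dis_weight must be >= 0")
        if not 0.0 <= self.rewrite_conf_gate <= 1.0:
            raise ValueError("rewrite_conf_gate must be in [0, 1]")
        if self.eval_ema is not None and not 0.0 < self.eval_ema < 1.0:
            raise ValueError("eval_ema must be in (0, 1) or None")


@dataclasses.dataclass
class EmbeddingState:
    """Running state of the inactive-data detector."""

    centroid: np.ndarray | None = None
    mu: float = 0.0
    sigma: float = 0.0
    threshold: float = np.inf
    beta: float = 0.0
    step: int = 0

    @property
    def initialized(self) -> bool:
        return self.centroid is not None


@dataclasses.dataclass
class PseudoLabelBatch:
    """Teacher predictions on an unlabeled sub-batch, before/after cleaning."""

    probs: np.ndarray  # (n, 6) soft predictions
    labels: np.ndarray  # (n,) hard pseudo labels
    scores: np.ndarray | None = None  # (n,) distance scores
    noise_mask: np.ndarray | None = None  # (n,) True = flagged inactive
    weights: np.ndarray | None = None  # (n,) student-loss weights

    def __post_init__(self):
        n = self.probs.shape[0]
        if self.noise_mask is None:
            self.noise_mask = np.zeros(n, dtype=bool)
        if self.weights is None:
            self.weights = np.ones(n)


@dataclasses.dataclass
class LossBreakdown:
    l_mpl: float = 0.0
    l_cons: float = 0.0
    l_uda: float = 0.0
    l_dis: float = 0.0
    teacher_total: float = 0.0
    student_loss: float = 0.0
    h: float = 0.0


class Batch(NamedTuple):
    labeled_x: np.ndarray  # (b, T, 12)
    labeled_y: np.ndarray
    unlabeled_x: np.ndarray  # (b, T, 12)
    unlabeled_idx: np.ndarray  # indices into the unlabeled pool
    weak: np.ndarray  # (b, T, 12)
    strong: np.ndarray  # (b, T, 12), strong ops applied in the 4D layout


class PseudoRecord(NamedTuple):
    step: int
    unlabeled_idx: np.ndarray
    labels: np.ndarray
    noise_mask: np.ndarray


@dataclasses.dataclass
class TrainResult:
    teacher: Backbone
    student: Backbone
    state: EmbeddingState
    losses: list[LossBreakdown]
    metrics_history: list  # (step, Metrics) pairs
    pseudo_log: list[PseudoRecord]
    embedding_history: list  # (step, mu, sigma, threshold, beta)


def _as_layout(batch_flat: np.ndarray, layout: str) -> np.ndarray:
    return reshape_4d(batch_flat) if layout == "4d" else batch_flat


def assemble_batch(
    labeled: WindowSet,
    unlabeled: WindowSet,
    cfg: TrainConfig,
    aug_cfg: AugmentationConfig,
    seed: int,
) -> Batch:
    """Draw equal labeled/unlabeled sub-batches and build the two views.

    Sampling is with replacement (pools may be smaller than a batch) and
    deterministic given ``seed``.  The strong view is produced in the 4D
    layout, where the (x, y, z) axis grouping that dimension shuffle permutes
    is explicit, then flattened back.
    """
    if len(labeled) == 0 or len(unlabeled) == 0:
        raise ValueError("labeled and unlabeled pools must be non-empty")
    rng = np.random.default_rng(seed)
    li = rng.integers(0, len(labeled), size=cfg.batch_size)
    ui = rng.integers(0, len(unlabeled), size=cfg.batch_size)
    ux = unlabeled.values[ui]
    weak = weak_augment_batch(ux, aug_cfg, int(rng.integers(2**31)))
    strong = flatten_4d(
        strong_augment_batch(reshape_4d(ux), aug_cfg, int(rng.integers(2**31)))
    )
    return Batch(labeled.values[li], labeled.labels[li], ux, ui, weak, strong)


def pseudo_label(teacher: Backbone, batch_flat: np.ndarray) -> PseudoLabelBatch:
    """Teacher soft predictions and argmax hard labels (ties → lowest index)."""
    out = teacher.forward(_as_layout(batch_flat, teacher.cfg.input_layout))
    probs = out.probabilities
    return PseudoLabelBatch(probs=probs, labels=np.argmax(probs, axis=-1))


def distance_scores_from_features(features: np.ndarray, state: EmbeddingState) -> np.ndarray:
    """S(x) = ||φ(x) − C||² per row."""
    if not state.initialized:
        raise ValueError("centroid not initialized")
    d = np.asarray(features) - state.centroid
    return np.einsum("ij,ij->i", d, d)


def distance_scores(teacher: Backbone, batch_flat: np.ndarray, state: EmbeddingState) -> np.ndarray:
    out = teacher.forward(_as_layout(batch_flat, teacher.cfg.input_layout))
    return distance_scores_from_features(out.features.data, state)


def clean_pseudo_labels(
    plb: PseudoLabelBatch, state: EmbeddingState, cfg: TrainConfig, active: bool = True
) -> PseudoLabelBatch:
    """Flag entries with S > T (strict) as inactive noise.

    ``active=False`` (warm-up) behaves as T = +∞.  In ``relabel`` mode the
    flagged pseudo labels become the inactive class; in ``exclude`` mode the
    flagged entries get zero student-loss weight.
    """
    if plb.scores is None:
        raise ValueError("distance scores must be computed before cleaning")
    threshold = state.threshold if active else np.inf
    mask = plb.scores > threshold
    labels = plb.labels.copy()
    weights = plb.weights.copy()
    if cfg.noise_mode == "relabel":
        labels[mask] = INACTIVE_LABEL
    else:
        weights[mask] = 0.0
    return PseudoLabelBatch(
        probs=plb.probs, labels=labels, scores=plb.scores, noise_mask=mask, weights=weights
    )


def student_step(
    student: Backbone,
    optimizer: nn.SGD,
    batch_flat: np.ndarray,
    plb: PseudoLabelBatch,
) -> float | None:
    """One SGD step on CE(cleaned ŷ_u, student(x_u)); returns the loss.

    Skipped (returns None) when every entry is excluded.
    """
    if plb.weights.sum() == 0:
        log.info("student step skipped: all unlabeled entries excluded")
        return None
    out = student.forward(_as_layout(batch_flat, student.cfg.input_layout))
    loss = nn.cross_entropy(out.logits, plb.labels, plb.weights)
    optimizer.zero_grad()
    loss.backward()
    optimizer.step()
    return float(loss.data)


def _labeled_ce(model: Backbone, labeled_x: np.ndarray, labeled_y: np.ndarray) -> float:
    out = model.forward(_as_layout(labeled_x, model.cfg.input_layout))
    return float(nn.cross_entropy(out.logits, labeled_y).data)


def compute_h(
    student: Backbone,
    state_before: list[np.ndarray],
    state_after: list[np.ndarray],
    labeled_x: np.ndarray,
    labeled_y: np.ndarray,
) -> float:
    """Scalar MPL feedback: labeled CE before minus after the student step.

    h > 0 means the pseudo labels improved the student on labeled data; the
    teacher is then rewarded for them through h·CE in :func:`mpl_loss`.  This
    sign makes the expected MPL gradient equal the true bilevel gradient
    (see the module docstring).
    """
    student.set_state(state_before)
    ce_before = _labeled_ce(student, labeled_x, labeled_y)
    student.set_state(state_after)
    ce_after = _labeled_ce(student, labeled_x, labeled_y)
    return ce_before - ce_after


def mpl_loss(
    h: float, teacher_logits: Tensor, pseudo_labels: np.ndarray, weights: np.ndarray | None = None
) -> Tensor:
    """L_MPL = h · CE(ŷ_u, teacher logits); ŷ_u are fixed targets."""
    return h * nn.cross_entropy(teacher_logits, pseudo_labels, weights)


def consistency_loss(weak_probs: np.ndarray, strong_logits: Tensor) -> Tensor:
    """CE between the (detached) weak-view prediction and the strong view."""
    if weak_probs.shape[0] != strong_logits.shape[0]:
        raise ValueError("weak/strong view length mismatch")
    return nn.soft_cross_entropy(strong_logits, weak_probs)


def uda_loss(labeled_logits: Tensor, labeled_y: np.ndarray, l_cons: Tensor | float) -> Tensor:
    """L_UDA = supervised CE on labeled data + consistency loss."""
    return nn.cross_entropy(labeled_logits, labeled_y) + l_cons


def distance_loss(features: Tensor, state: EmbeddingState) -> Tensor:
    """Mean squared distance of labeled features to the centroid (C fixed)."""
    if not state.initialized:
        raise ValueError("centroid not initialized")
    d = features - Tensor(state.centroid)
    return (d * d).sum(axis=-1).mean()


def update_centroid(state: EmbeddingState, features: np.ndarray, eta_c: float) -> EmbeddingState:
    """Exponential step of C toward the labeled-batch feature mean.

    C ← C − η_C (C − mean φ); η_C = 1 jumps straight to the batch mean.
    """
    if not 0 < eta_c <= 1:
        raise ValueError("eta_c must be in (0, 1]")
    mean = np.asarray(features).mean(axis=0)
    if not state.initialized:
        state.centroid = mean.copy()
    else:
        state.centroid = state.centroid - eta_c * (state.centroid - mean)
    return state

def update_threshold(
    state: EmbeddingState, scores: np.ndarray, alpha: float, beta_t: float
) -> EmbeddingState:
    """EMA updates of μ and σ from labeled-batch scores, then T = μ + β·σ."""
    scores = np.asarray(scores)
    state.mu = alpha * float(scores.mean()) + (1 - alpha) * state.mu
    state.sigma = alpha * float(scores.std()) + (1 - alpha) * state.sigma
    state.beta = beta_t
    state.threshold = state.mu + beta_t * state.sigma
    return state


def beta_schedule(cfg: TrainConfig, step: int) -> float:
    """Linear ramp beta_start → beta_end over the run."""
    if cfg.total_steps <= 1:
        return cfg.beta_end
    frac = min(max(step / (cfg.total_steps - 1), 0.0), 1.0)
    return cfg.beta_start + frac * (cfg.beta_end - cfg.beta_start)


def teacher_step(optimizer: nn.SGD, total_loss: Tensor, breakdown: LossBreakdown) -> None:
    """One SGD step on the combined teacher loss; aborts on non-finite loss."""
    if not np.isfinite(total_loss.data):
        raise FloatingPointError(f"non-finite teacher loss: {breakdown}")
    optimizer.zero_grad()
    total_loss.backward()
    optimizer.step()


def desk_preset(**overrides) -> TrainConfig:
    """Desk-scale preset: small batches, 2,000 steps, constant SGD.

    The problem sizes here are what a single CPU core handles in about a
    minute per run; they pair with the default synthetic pools (40 labeled
    windows per class, 300 unlabeled).
    """
    base = dict(batch_size=16, total_steps=2000, log_every=100)
    base.update(overrides)
    return TrainConfig(**base)


def train(
    labeled: WindowSet,
    unlabeled: WindowSet,
    test: WindowSet,
    cfg: TrainConfig,
    model_cfg: BackboneConfig | None = None,
    aug_cfg: AugmentationConfig | None = None,
) -> TrainResult:
    """Run the full CMPL loop; see the module docstring for the algorithm.

    Per step: assemble → pseudo-label → distance scores → clean → student
    step → h → teacher losses → teacher step → centroid/threshold updates.
    With ``mpl_enabled=False``, ``uda_enabled=False`` and
    ``cleaning_enabled=False`` the loop degenerates to supervised training of
    the teacher on labeled data.  Fully reproducible given ``cfg.seed``.
    """
    cfg.validate()
    if model_cfg is None:
        model_cfg = BackboneConfig()
    if aug_cfg is None:
        aug_cfg = AugmentationConfig()
    rng = np.random.default_rng(cfg.seed)
    teacher = build_model(model_cfg, int(rng.integers(2**31)))
    student = build_model(model_cfg, int(rng.integers(2**31)))
    t_opt = nn.SGD(teacher.parameters(), cfg.teacher_lr, cfg.momentum, cfg.clip_norm)
    s_opt = nn.SGD(student.parameters(), cfg.student_lr, cfg.momentum, cfg.clip_norm)
    state = EmbeddingState()
    layout = model_cfg.input_layout
    warmup_steps = int(cfg.warmup_frac * cfg.total_steps)

    losses: list[LossBreakdown] = []
    pseudo_log: list[PseudoRecord] = []
    metrics_history: list = []
    embedding_history: list = []

    # Polyak-averaged parameter copies; plain SGD endpoints are noisy, so
    # test metrics are read off these smoothed weights
    ema_t = teacher.get_state() if cfg.eval_ema else None
    ema_s = student.get_state() if cfg.eval_ema else None

    def ema_update() -> None:
        d = cfg.eval_ema
        for tracked, model in ((ema_t, teacher), (ema_s, student)):
            for avg, cur in zip(tracked, model.get_state()):
                avg *= d
                avg += (1 - d) * cur

    from .evaluation import compute_metrics  # local import avoids a cycle

    def evaluate(step: int) -> None:
        primary = student if cfg.mpl_enabled else teacher
        raw_state = None
        if cfg.eval_ema:
            raw_state = primary.get_state()
            primary.set_state(ema_s if cfg.mpl_enabled else ema_t)
        out = primary.forward(_as_layout(test.values, layout))
        preds = np.argmax(out.logits.data, axis=-1)
        test_loss = float(nn.cross_entropy(out.logits, test.labels).data)
        if raw_state is not None:
            primary.set_state(raw_state)
        metrics_history.append((step, compute_metrics(preds, test.labels, test_loss)))

    for step in range(cfg.total_steps):
        batch = assemble_batch(labeled, unlabeled, cfg, aug_cfg, int(rng.integers(2**31)))
        bd = LossBreakdown()

        # teacher on labeled data: CE, features for L_dis / centroid / scores
        out_l = teacher.forward(_as_layout(batch.labeled_x, layout))
        feats_l = out_l.features.data.copy()
        if not state.initialized:
            update_centroid(state, feats_l, cfg.centroid_lr)
            scores_l0 = distance_scores_from_features(feats_l, state)
            state.mu = float(scores_l0.mean())
            state.sigma = float(scores_l0.std())
            state.beta = beta_schedule(cfg, step)
            state.threshold = state.mu + state.beta * state.sigma

        total = uda_loss(out_l.logits, batch.labeled_y, 0.0)
        bd.l_uda = float(total.data)

        if cfg.mpl_enabled:
            pl_view = batch.weak if cfg.pseudo_view == "weak" else batch.unlabeled_x
            out_u = teacher.forward(_as_layout(pl_view, layout))
            probs_u = out_u.probabilities
            plb = PseudoLabelBatch(probs=probs_u, labels=np.argmax(probs_u, axis=-1))
            # distance scores are defined on the raw unlabeled window, not a view
            if cfg.pseudo_view == "raw":
                plb.scores = distance_scores_from_features(out_u.features.data, state)
            else:
                plb.scores = distance_scores(teacher, batch.unlabeled_x, state)
            cleaning_active = cfg.cleaning_enabled and step >= warmup_steps
            plb = clean_pseudo_labels(plb, state, cfg, active=cleaning_active)
            if cleaning_active and cfg.noise_mode == "relabel" and plb.noise_mask.any():
                # confidence veto: a window the teacher still confidently
                # assigns to a behavior keeps its pseudo label — the distance
                # rule flags it, but relabeling it as noise would feed a
                # false flag back into training
                spared = plb.noise_mask & (
                    plb.probs[:, :5].max(axis=1) >= cfg.rewrite_conf_gate
                )
                if spared.any():
                    plb.noise_mask = plb.noise_mask & ~spared
                    plb.labels[spared] = np.argmax(plb.probs[spared], axis=-1)

            before = student.get_state()
            s_loss = student_step(student, s_opt, batch.unlabeled_x, plb)
            if s_loss is not None:
                after = student.get_state()
                bd.h = compute_h(student, before, after, batch.labeled_x, batch.labeled_y)
                bd.student_loss = s_loss
                l_mpl = mpl_loss(bd.h, out_u.logits, plb.labels, plb.weights)
                bd.l_mpl = float(l_mpl.data)
                total = total + l_mpl
            if cfg.log_every and step % cfg.log_every == 0:
                pseudo_log.append(
                    PseudoRecord(step, batch.unlabeled_idx, plb.labels.copy(), plb.noise_mask.copy())
                )

        if cfg.uda_enabled:
            if not cfg.mpl_enabled or cfg.pseudo_view != "weak":
                out_w = teacher.forward(_as_layout(batch.weak, layout))
                weak_probs = out_w.probabilities
            else:
                weak_probs = probs_u
            if cfg.mpl_enabled and cfg.cleaning_enabled and cfg.noise_mode == "relabel":
                # cleaning rewrites the teacher's output: flagged windows'
                # consistency target becomes the inactive class (the mask has
                # already been confidence-vetoed above)
                flagged = plb.noise_mask
                if flagged.any():
                    weak_probs = weak_probs.copy()
                    weak_probs[flagged] = 0.0
                    weak_probs[flagged, INACTIVE_LABEL] = 1.0
            out_s = teacher.forward(_as_layout(batch.strong, layout))
            l_cons = consistency_loss(weak_probs, out_s.logits)
            bd.l_cons = float(l_cons.data)
            bd.l_uda += bd.l_cons
            total = total + l_cons

        if cfg.cleaning_enabled:
            # center-loss style weighting: compression must not overpower
            # the supervised signal
            l_dis = distance_loss(out_l.features, state) * cfg.dis_weight
            bd.l_dis = float(l_dis.data)
            total = total + l_dis

        bd.teacher_total = float(total.data)
        teacher_step(t_opt, total, bd)

        if cfg.cleaning_enabled:
            update_centroid(state, feats_l, cfg.centroid_lr)
            scores_l = distance_scores_from_features(feats_l, state)
            update_threshold(state, scores_l, cfg.ema_alpha, beta_schedule(cfg, step))
        if cfg.eval_ema:
            ema_update()
        state.step = step + 1
        losses.append(bd)
        if cfg.log_every and step % cfg.log_every == 0:
            embedding_history.append((step, state.mu, state.sigma, state.threshold, state.beta))
        if cfg.eval_every and (step + 1) % cfg.eval_every == 0:
            evaluate(step + 1)

    if len(test) > 0:
        evaluate(cfg.total_steps)
    return TrainResult(teacher, student, state, losses, metrics_history, pseudo_log, embedding_history)


def detect_inactive(
    teacher: Backbone, pool: WindowSet, state: EmbeddingState, chunk: int = 256
) -> tuple[np.ndarray, np.ndarray]:
    """Score a whole pool against the final threshold.

    Returns ``(flagged, scores)`` where ``flagged[i]`` is True when window i
    scores above T — the trained detector's verdict that it is inactive.
    """
    scores = np.empty(len(pool))
    for start in range(0, len(pool), chunk):
        part = pool.values[start : start + chunk]
        scores[start : start + chunk] = distance_scores(teacher, part, state)
    return scores > state.threshold, scores
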