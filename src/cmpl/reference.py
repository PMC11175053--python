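"""Straight-line reference training loops.

These deliberately re-state the degenerate cases of the CMPL loop in plain
code — supervised cross-entropy training, and textbook meta pseudo labels
with no consistency or cleaning machinery — so the full loop can be checked
to collapse onto them exactly when its extra components are switched off.
They share only the low-level layers, the batch sampler and the seed
discipline with the main loop; the update logic is written out here
independently.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .augmentation import AugmentationConfig
from .model import BackboneConfig, build_model
from .preprocessing import reshape_4d
from .synthetic_data import WindowSet
from .training import TrainConfig, assemble_batch

__all__ = ["supervised_reference", "mpl_reference"]


def _prep(x: np.ndarray, layout: str) -> np.ndarray:
    return reshape_4d(x) if layout == "4d" else x


def supervised_reference(
    labeled: WindowSet,
    unlabeled: WindowSet,
    cfg: TrainConfig,
    model_cfg: BackboneConfig | None = None,
    aug_cfg: AugmentationConfig | None = None,
):
    """Plain supervised SGD on labeled windows.

    Batches are drawn with the same sampler and seed stream as the CMPL loop
    (the unlabeled half of each batch is drawn and discarded) so histories
    are directly comparable.  Returns (model, per-step losses).
    """
    if model_cfg is None:
        model_cfg = BackboneConfig()
    if aug_cfg is None:
        aug_cfg = AugmentationConfig()
    rng = np.random.default_rng(cfg.seed)
    teacher = build_model(model_cfg, int(rng.integers(2**31)))
    rng.integers(2**31)  # student slot in the seed stream, unused here
    opt = nn.SGD(teacher.parameters(), cfg.teacher_lr, cfg.momentum, cfg.clip_norm)
    losses = []
    for _ in range(cfg.total_steps):
        batch = assemble_batch(labeled, unlabeled, cfg, aug_cfg, int(rng.integers(2**31)))
        out = teacher.forward(_prep(batch.labeled_x, model_cfg.input_layout))
        loss = nn.cross_entropy(out.logits, batch.labeled_y)
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(float(loss.data))
    return teacher, losses


def mpl_reference(
    labeled: WindowSet,
    unlabeled: WindowSet,
    cfg: TrainConfig,
    model_cfg: BackboneConfig | None = None,
    aug_cfg: AugmentationConfig | None = None,
):
    """Textbook meta pseudo labels, nothing else.

    Teacher labels the plain unlabeled batch; student takes one SGD step on
    those hard labels; the labeled-loss improvement h = CE_before − CE_after
    weights the teacher's CE on its own pseudo labels; the teacher also gets
    supervised CE.  Returns (teacher, student, per-step teacher losses).
    """
    if model_cfg is None:
        model_cfg = BackboneConfig()
    if aug_cfg is None:
        aug_cfg = AugmentationConfig()
    layout = model_cfg.input_layout
    rng = np.random.default_rng(cfg.seed)
    teacher = build_model(model_cfg, int(rng.integers(2**31)))
    student = build_model(model_cfg, int(rng.integers(2**31)))
    t_opt = nn.SGD(teacher.parameters(), cfg.teacher_lr, cfg.momentum, cfg.clip_norm)
    s_opt = nn.SGD(student.parameters(), cfg.student_lr, cfg.momentum, cfg.clip_norm)
    losses = []
    for _ in range(cfg.total_steps):
        batch = assemble_batch(labeled, unlabeled, cfg, aug_cfg, int(rng.integers(2**31)))
        out_l = teacher.forward(_prep(batch.labeled_x, layout))
        ce_l = nn.cross_entropy(out_l.logits, batch.labeled_y)
        out_u = teacher.forward(_prep(batch.unlabeled_x, layout))
        pseudo = np.argmax(out_u.probabilities, axis=-1)

        s_out = student.forward(_prep(batch.unlabeled_x, layout))
        s_loss = nn.cross_entropy(s_out.logits, pseudo)
        before = student.get_state()
        s_opt.zero_grad()
        s_loss.backward()
        s_opt.step()
        after = student.get_state()

        def labeled_ce(state):
            student.set_state(state)
            out = student.forward(_prep(batch.labeled_x, layout))
            return float(nn.cross_entropy(out.logits, batch.labeled_y).data)

        h = labeled_ce(before) - labeled_ce(after)
        student.set_state(after)

        total = ce_l + h * nn.cross_entropy(out_u.logits, pseudo)
        t_opt.zero_grad()
        total.backward()
        t_opt.step()
        losses.append(float(total.data))
    return teacher, student, losses
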