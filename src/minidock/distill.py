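"""Ensemble knowledge distillation for pose scorers.

A single student is trained to reproduce the pose-score behavior of an
ensemble of teachers while keeping ground-truth supervision: the KD loss is
the sum over teachers of the KL divergence between teacher and student pose
distributions (the logits are tempered and softmaxed inside the loss), and
the total loss adds the supervised pose cross entropy and hinged affinity
losses. Distillation considers the pose score only; affinity remains
supervised by ground truth alone. A "soft-target cross entropy" variant
(against the mean teacher distribution) is available as a configuration
switch since the combination rule is a design choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cnn_models import (
    GridScorer,
    ModelSpec,
    TrainConfig,
    TrainingExample,
    _batch_losses,
    build_model,
    stack_grids,
)
from .errors import InputError, ScoringError
from .nn import SGD, log_softmax, random_grid_rotation, softmax


@dataclass
class DistillConfig:
    student_spec: ModelSpec
    kd_weight: float = 1.0
    temperature: float = 1.0
    kd_mode: str = "kl"  # "kl" (per-teacher) or "soft_ce" (mean teacher)
    train: TrainConfig = field(default_factory=TrainConfig)
    heldout_fraction: float = 0.25

    def __post_init__(self):
        if self.kd_weight < 0:
            raise InputError("KD weight must be >= 0")
        if self.kd_mode not in ("kl", "soft_ce"):
            raise InputError("kd_mode must be 'kl' or 'soft_ce'")


def kd_loss(
    student_logits: np.ndarray,
    teacher_logits_list: list[np.ndarray],
    temperature: float = 1.0,
) -> float:
    """Sum over teachers of KL(teacher || student) on tempered softmax
    distributions, averaged over the batch."""
    s = np.atleast_2d(student_logits) / temperature
    ls = log_softmax(s)
    total = 0.0
    for t_logits in teacher_logits_list:
        t = np.atleast_2d(t_logits) / temperature
        pt = softmax(t)
        lt = log_softmax(t)
        total += float((pt * (lt - ls)).sum(axis=1).mean())
    return total


def _kd_grad(student_logits, teacher_logits_list, temperature):
    """d(kd_loss)/d(student_logits), batch-mean convention."""
    bsz = student_logits.shape[0]
    ps = softmax(student_logits / temperature)
    g = np.zeros_like(student_logits)
    for t_logits in teacher_logits_list:
        pt = softmax(t_logits / temperature)
        g += (ps - pt) / temperature
    return g / bsz


def total_distill_loss(
    student_output,
    teacher_logits_list: list[np.ndarray],
    pose_label: bool,
    true_affinity: float,
    config: DistillConfig,
) -> float:
    """kd_weight * KD + pose cross entropy + hinged affinity loss (single
    example convenience; training uses the batched equivalent)."""
    from .cnn_models import hinged_affinity_loss, pose_classification_loss

    kd = kd_loss(
        student_output.logits, teacher_logits_list, config.temperature
    )
    ce = pose_classification_loss(student_output, pose_label)
    aff = hinged_affinity_loss(student_output.affinity, true_affinity, pose_label)
    return config.kd_weight * kd + ce + aff


def kl_two_class(p_good_a: np.ndarray, p_good_b: np.ndarray) -> np.ndarray:
    """KL(a || b) between two-class distributions given P(good)."""
    pa = np.clip(np.asarray(p_good_a, dtype=float), 1e-12, 1 - 1e-12)
    pb = np.clip(np.asarray(p_good_b, dtype=float), 1e-12, 1 - 1e-12)
    return pa * np.log(pa / pb) + (1 - pa) * np.log((1 - pa) / (1 - pb))


def student_ensemble_kl(
    student: GridScorer, teachers: list[GridScorer], grids: np.ndarray
) -> float:
    """Mean KL(student || ensemble-mean pose distribution) over grids."""
    s_logits, _ = student.forward_batch(grids)
    ps = softmax(s_logits)[:, 1]
    pt = np.mean(
        [softmax(t.forward_batch(grids)[0])[:, 1] for t in teachers], axis=0
    )
    return float(kl_two_class(ps, pt).mean())


def distill_student(
    teachers: list[GridScorer],
    dataset: list[TrainingExample],
    config: DistillConfig,
    heldout: list[TrainingExample] | None = None,
) -> tuple[GridScorer, dict]:
    """Train a student on the teachers' training data with the combined KD +
    supervised loss; returns the student and a fidelity report with the mean
    held-out KL to the ensemble."""
    if len(teachers) < 1:
        raise InputError("at least one teacher required")
    if heldout is None:
        n_held = max(1, int(len(dataset) * config.heldout_fraction))
        heldout = dataset[-n_held:]
        dataset = dataset[:-n_held]

    student = build_model(config.student_spec)
    tc = config.train
    grids, labels, aff = stack_grids(dataset)
    rng = np.random.default_rng(tc.seed)
    opt = SGD(student.parameters(), lr=tc.lr, momentum=tc.momentum)
    n = len(dataset)
    history = {"pose_loss": [], "affinity_loss": [], "kd_loss": []}

    # teacher logits on the un-augmented grids, computed once
    teacher_logits_full = [t.forward_batch(grids)[0] for t in teachers]

    for _ in range(tc.epochs):
        order = rng.permutation(n)
        ce_sum = aff_sum = kd_sum = 0.0
        for start in range(0, n, tc.batch_size):
            idx = order[start : start + tc.batch_size]
            batch = grids[idx]
            if tc.augment:
                # same rotation seen by student and teachers
                batch = np.stack([random_grid_rotation(g, rng) for g in batch])
                t_logits = [t.forward_batch(batch)[0] for t in teachers]
            else:
                t_logits = [tl[idx] for tl in teacher_logits_full]
            logits, affinity = student.forward_batch(batch)
            ce, aff_loss, dlogits, daff = _batch_losses(
                logits, affinity, labels[idx], aff[idx]
            )
            kd = kd_loss(logits, t_logits, config.temperature)
            if config.kd_mode == "kl":
                dkd = _kd_grad(logits, t_logits, config.temperature)
            else:
                # soft-target CE against the mean teacher distribution
                pt = np.mean(
                    [softmax(tl / config.temperature) for tl in t_logits], axis=0
                )
                dkd = (softmax(logits / config.temperature) - pt) / (
                    config.temperature * len(idx)
                )
            if not np.isfinite(kd):
                raise ScoringError("distillation diverged")
            student.backward_batch(
                dlogits + config.kd_weight * dkd, tc.affinity_weight * daff
            )
            opt.step()
            ce_sum += ce * len(idx)
            aff_sum += aff_loss * len(idx)
            kd_sum += kd * len(idx)
        history["pose_loss"].append(ce_sum / n)
        history["affinity_loss"].append(aff_sum / n)
        history["kd_loss"].append(kd_sum / n)

    held_grids, _, _ = stack_grids(heldout)
    report = {
        "heldout_kl_to_ensemble": student_ensemble_kl(
            student, teachers, held_grids
        ),
        "history": history,
        "n_train": n,
        "n_heldout": len(heldout),
    }
    return student, report
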