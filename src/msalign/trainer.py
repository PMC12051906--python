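"""Training and evaluation of cross-domain seizure-detection transfer tasks.

A :class:`TransferTask` bundles a labeled source domain, a target domain,
the transfer scenario (unsupervised or semi-supervised with the first l% of
each target subject's per-class clips labeled) and drives the experiment
protocols: multi-space alignment training, the comparison baselines
(source-only, within, combined, channel truncation), per-subject AUC
evaluation and seeded repeats.

Target trials are split chronologically per subject and per class so that
no test clip precedes a labeled training clip of the same subject and class
(the temporal-leakage guard).  Unlabeled target clips are used
transductively for the adaptation and distillation terms — their labels are
never read during training; an ``inductive`` flag disables this.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import roc_auc_score

from . import nn
from .alignment_losses import (
    LossWeights,
    cross_entropy,
    kd_loss,
    mcc_loss,
    mmd_loss,
    msa_total_loss,
)
from .data_io import DomainDataset, Trial, resample_trial
from .euclidean_alignment import euclidean_align
from .models import EEGNet, EEGNetConfig, MSAModel, ResizeNet, truncate_channels
from .nn import Tensor

logger = logging.getLogger(__name__)

__all__ = [
    "TransferTask",
    "TrainConfig",
    "MethodConfig",
    "EvalResult",
    "chronological_label_split",
    "prepare_task",
    "train_msa",
    "train_baseline",
    "evaluate_auc",
    "run_experiment",
    "run_repeated_experiment",
    "ablation_ladder",
    "ABLATION_STEPS",
]

LABEL_FRACTIONS = (0, 5, 10, 15, 20)


@dataclass
class TransferTask:
    """One transfer experiment: labeled source domain -> target domain."""

    source: DomainDataset
    target: DomainDataset
    scenario: str = "unsupervised"  # or "semi_supervised"
    label_fraction: int = 0  # l%, per subject and per class

    def __post_init__(self):
        if self.scenario not in ("unsupervised", "semi_supervised"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.scenario == "unsupervised" and self.label_fraction != 0:
            raise ValueError("unsupervised transfer implies label_fraction = 0")
        if self.scenario == "semi_supervised" and not 0 < self.label_fraction < 100:
            raise ValueError("semi-supervised transfer needs 0 < l < 100")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 35
    batch_size: int = 64  # per domain
    learning_rate: float = 1e-3
    # the distillation and adaptation weights ramp linearly from 0 to their
    # configured values over this fraction of training, so the early epochs
    # are driven by the supervised signal alone
    warmup_frac: float = 0.5
    seed: int = 0
    deterministic: bool = True
    repeats: int = 3

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 4:
            raise ValueError("batch_size must be >= 4")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass(frozen=True)
class MethodConfig:
    """Which alignment spaces a training run uses."""

    name: str = "msa"
    use_ea: bool = True          # input-space whitening
    use_resizenet: bool = True   # learnable channel projection (else truncation)
    da: str = "mcc"              # feature-space term: mcc | mmd | none
    kd: str = "logit"            # output-space term: logit | none
    # the full-montage projection branch sees strictly more information, so
    # it acts as the teacher and the channel-selection branch as the student
    kd_direction: str = "resize_teacher"  # | "truncation_teacher" | "mutual"
    use_source: bool = True
    use_target_labels: bool = True  # honor the semi-supervised labeled pool


# full multi-space alignment and the comparison ladder
MSA_METHOD = MethodConfig(name="msa")
ABLATION_STEPS: tuple[MethodConfig, ...] = (
    MethodConfig(name="none", use_ea=False, use_resizenet=False, da="none", kd="none"),
    MethodConfig(name="+EA", use_ea=True, use_resizenet=False, da="none", kd="none"),
    MethodConfig(name="+DA", use_ea=True, use_resizenet=True, da="mcc", kd="none"),
    MethodConfig(name="full", use_ea=True, use_resizenet=True, da="mcc", kd="logit"),
)

BASELINE_VARIANTS = ("source_only", "within", "comb", "truncation_noalign")


@dataclass
class EvalResult:
    """Subject-averaged AUCs over seeded repeats."""

    per_subject_auc: dict[str, float]  # averaged over repeats
    mean_auc: float
    std_auc: float
    seeds: list[int]
    per_repeat_mean: list[float] = field(default_factory=list)


# ----------------------------------------------------------------------
# splitting
# ----------------------------------------------------------------------

def chronological_label_split(
    dataset: DomainDataset, label_fraction: float
) -> tuple[list[Trial], list[Trial]]:
    """Per subject and per class, send the chronologically first
    ceil(l% * n_class) trials to the labeled pool and the rest to the test
    pool.  Pools are disjoint and exhaustive, and within every subject and
    class all labeled clips precede all test clips.
    """
    if not 0 < label_fraction < 100:
        raise ValueError("label_fraction must be in (0, 100)")
    labeled: list[Trial] = []
    test: list[Trial] = []
    for sid in dataset.subjects:
        trials = dataset.subject_trials(sid)  # already sorted by start_time
        for cls in (0, 1):
            cls_trials = [t for t in trials if t.label == cls]
            if not cls_trials:
                warnings.warn(f"subject {sid} has no trials of class {cls}")
                continue
            k = math.ceil(label_fraction / 100.0 * len(cls_trials))
            labeled.extend(cls_trials[:k])
            test.extend(cls_trials[k:])
    return labeled, test


def prepare_task(task: TransferTask, use_ea: bool = True) -> TransferTask:
    """Bring both domains to the lower of the two sampling rates and
    (optionally) Euclidean-align each domain per subject."""
    src, tgt = task.source, task.target
    common = min(src.sampling_rate, tgt.sampling_rate)
    src = _resample_dataset(src, common)
    tgt = _resample_dataset(tgt, common)
    if use_ea:
        src, _ = euclidean_align(src)
        tgt, _ = euclidean_align(tgt)
    return replace(task, source=src, target=tgt)


def _resample_dataset(ds: DomainDataset, to_rate: float) -> DomainDataset:
    if ds.sampling_rate == to_rate:
        return ds
    trials = [resample_trial(t, ds.sampling_rate, to_rate) for t in ds.trials]
    return DomainDataset(trials, ds.n_channels, to_rate, ds.modality,
                         ds.species, ds.domain_id)


# ----------------------------------------------------------------------
# evaluation
# ----------------------------------------------------------------------

def evaluate_auc(
    model: MSAModel, test: list[Trial], batch_size: int = 256
) -> dict[str, float]:
    """Per-subject AUC of the model's seizure probability (rank statistic,
    half credit for ties).  Subjects whose test pool lacks a class are
    skipped with a log message."""
    subjects: dict[str, list[Trial]] = {}
    for t in test:
        subjects.setdefault(t.subject_id, []).append(t)
    out: dict[str, float] = {}
    for sid, trials in subjects.items():
        labels = np.array([t.label for t in trials])
        if len(np.unique(labels[labels >= 0])) < 2:
            logger.info("subject %s skipped: test pool lacks a class", sid)
            continue
        X = np.stack([t.signal for t in trials])
        scores = np.concatenate(
            [model.predict_proba(X[i : i + batch_size])
             for i in range(0, len(X), batch_size)]
        )
        out[sid] = float(roc_auc_score(labels, scores))
    return out


# ----------------------------------------------------------------------
# training
# ----------------------------------------------------------------------

def _stack(trials: list[Trial]) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([t.signal for t in trials]).astype(np.float32)
    y = np.array([t.label for t in trials], dtype=np.int64)
    return X, y


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        b = order[i : i + batch_size]
        if len(b) >= 2:  # batch-norm and the DA losses need >= 2 examples
            yield b


class _Cycler:
    """Endless shuffled index stream over a pool."""

    def __init__(self, n: int, batch_size: int, rng: np.random.Generator):
        self.n, self.bs, self.rng = n, batch_size, rng
        self._order = rng.permutation(n)
        self._pos = 0

    def next(self) -> np.ndarray:
        if self._pos + self.bs > self.n:
            self._order = self.rng.permutation(self.n)
            self._pos = 0
        out = self._order[self._pos : self._pos + self.bs]
        self._pos += self.bs
        return out


def _build_model(
    c_source: int, c_target: int, n_samples: int, sampling_rate: float,
    method: MethodConfig, loss_w: LossWeights, rng: np.random.Generator,
) -> MSAModel:
    cfg = EEGNetConfig(
        n_channels=c_target,
        n_samples=n_samples,
        kernel_length=max(2, int(sampling_rate // 2)),
    )
    backbone = EEGNet(cfg, rng)
    resizenet = (
        ResizeNet(c_source, c_target)
        if method.use_resizenet and c_source != c_target
        else None
    )
    return MSAModel(
        backbone=backbone,
        resizenet=resizenet,
        lambda_kd=loss_w.lambda_kd,
        beta_da=loss_w.beta_da,
        tau_kd=loss_w.tau_kd,
        tau_mcc=loss_w.tau_mcc,
    )


def _train_one(
    task: TransferTask,
    method: MethodConfig,
    loss_w: LossWeights,
    train_cfg: TrainConfig,
    seed: int,
    inductive: bool = False,
) -> tuple[MSAModel, list[Trial], dict]:
    """Train one model on an already-prepared task.

    Returns (model, target test pool, per-epoch loss history).
    """
    src, tgt = task.source, task.target
    c_src, c_tgt = src.n_channels, tgt.n_channels
    if c_src < c_tgt:
        raise ValueError(
            "the source montage must have at least as many channels as the"
            " target; swap the task or project the wider domain down"
        )

    # labeled / unlabeled / test pools
    if task.scenario == "semi_supervised":
        tgt_labeled, tgt_test = chronological_label_split(tgt, task.label_fraction)
    else:
        tgt_labeled, tgt_test = [], list(tgt.trials)
    if not method.use_target_labels:
        tgt_test = tgt_test + tgt_labeled
        tgt_labeled = []
    tgt_unlabeled = list(tgt.trials) if not inductive else tgt_labeled
    needs_target = method.da != "none"
    if needs_target and not tgt_unlabeled:
        raise ValueError("domain adaptation requires unlabeled target data")

    rng = np.random.default_rng(seed)
    model = _build_model(c_src, c_tgt, _n_samples(task), src.sampling_rate,
                         method, loss_w, rng)
    opt = nn.Adam(model.parameters(), lr=train_cfg.learning_rate)

    Xs, ys = _stack(src.trials) if method.use_source and len(src.trials) else (None, None)
    Xtl, ytl = _stack(tgt_labeled) if tgt_labeled else (None, None)
    Xtu = (np.stack([t.signal for t in tgt_unlabeled]).astype(np.float32)
           if tgt_unlabeled else None)
    if Xs is None and Xtl is None:
        raise ValueError("no labeled data: nothing to train on")

    n_anchor = len(Xs) if Xs is not None else len(Xtl)
    tl_cycle = (_Cycler(len(Xtl), min(train_cfg.batch_size, len(Xtl)), rng)
                if Xtl is not None else None)
    tu_cycle = (_Cycler(len(Xtu), min(train_cfg.batch_size, len(Xtu)), rng)
                if (Xtu is not None and needs_target) else None)

    history: dict[str, list[float]] = {"total": [], "ce": [], "kd": [], "da": []}
    use_kd = (method.kd == "logit" and model.resizenet is not None)
    total_steps = max(
        1, train_cfg.epochs * max(1, n_anchor // train_cfg.batch_size)
    )
    global_step = 0
    for _epoch in range(train_cfg.epochs):
        model.train()
        ep = {"total": 0.0, "ce": 0.0, "kd": 0.0, "da": 0.0}
        n_steps = 0
        for idx in _batches(n_anchor, train_cfg.batch_size, rng):
            logits_parts, label_parts = [], []
            feats_s = logits_resize = None
            if Xs is not None:
                xs = Tensor(Xs[idx])
                if model.resizenet is not None:
                    proj = model.project(xs)
                else:
                    proj = Tensor(truncate_channels(Xs[idx], c_tgt))
                feats_s, logits_resize = model.backbone(proj)
                logits_parts.append(logits_resize)
                label_parts.append(ys[idx])
            if tl_cycle is not None:
                j = tl_cycle.next()
                _, logits_tl = model.backbone(Tensor(Xtl[j]))
                logits_parts.append(logits_tl)
                label_parts.append(ytl[j])

            kd = Tensor(0.0)
            if use_kd and Xs is not None:
                # the channel-selection branch: the same backbone fed the
                # truncated montage.  It is supervised like the projection
                # branch (both are full input-unification strategies) and the
                # distillation term then aligns the two strategies' outputs;
                # kd_loss blocks the gradient on its teacher argument.
                trunc_in = Tensor(truncate_channels(Xs[idx], c_tgt))
                _, logits_trunc = model.backbone(trunc_in)
                logits_parts.append(logits_trunc)
                label_parts.append(ys[idx])
                if method.kd_direction == "resize_teacher":
                    kd = kd_loss(logits_trunc, logits_resize, loss_w.tau_kd)
                elif method.kd_direction == "truncation_teacher":
                    kd = kd_loss(logits_resize, logits_trunc, loss_w.tau_kd)
                elif method.kd_direction == "mutual":
                    kd = (kd_loss(logits_resize, logits_trunc, loss_w.tau_kd)
                          + kd_loss(logits_trunc, logits_resize, loss_w.tau_kd)) * 0.5
                else:
                    raise ValueError(f"unknown kd_direction {method.kd_direction!r}")

            ce = cross_entropy(nn.concat(logits_parts, axis=0) if len(logits_parts) > 1
                               else logits_parts[0],
                               np.concatenate(label_parts))

            da = Tensor(0.0)
            if tu_cycle is not None:
                k = tu_cycle.next()
                feats_t, logits_t = model.backbone(Tensor(Xtu[k]))
                if method.da == "mcc":
                    da = mcc_loss(logits_t, loss_w.tau_mcc)
                elif method.da == "mmd":
                    if feats_s is None:
                        raise ValueError("MMD needs source features")
                    da = mmd_loss(feats_s, feats_t)
                else:
                    raise ValueError(f"unknown da loss {method.da!r}")

            if train_cfg.warmup_frac > 0:
                ramp = min(1.0, global_step / (train_cfg.warmup_frac * total_steps))
            else:
                ramp = 1.0
            step_w = LossWeights(
                lambda_kd=loss_w.lambda_kd * ramp,
                beta_da=loss_w.beta_da * ramp,
                tau_kd=loss_w.tau_kd,
                tau_mcc=loss_w.tau_mcc,
            )
            total = msa_total_loss(ce, kd, da, step_w)
            opt.zero_grad()
            total.backward()
            opt.step()
            global_step += 1
            ep["total"] += total.item()
            ep["ce"] += ce.item()
            ep["kd"] += kd.item()
            ep["da"] += da.item()
            n_steps += 1
        for k in ep:
            history[k].append(ep[k] / max(n_steps, 1))
    model.eval()
    return model, tgt_test, history


def _n_samples(task: TransferTask) -> int:
    n_src = task.source.trials[0].n_samples if task.source.trials else None
    n_tgt = task.target.trials[0].n_samples if task.target.trials else None
    if n_src is not None and n_tgt is not None and n_src != n_tgt:
        raise ValueError(
            f"source and target clip lengths differ ({n_src} vs {n_tgt});"
            " resample to a common rate first (prepare_task)"
        )
    return n_tgt if n_tgt is not None else n_src


# ----------------------------------------------------------------------
# public training entry points
# ----------------------------------------------------------------------

def train_msa(
    task: TransferTask,
    loss_weights: LossWeights | None = None,
    train_cfg: TrainConfig | None = None,
    method: MethodConfig | None = None,
    inductive: bool = False,
) -> tuple[MSAModel, list[Trial], dict]:
    """Train the full multi-space alignment model on a prepared task.

    The task must already be at a common sampling rate (and Euclidean-
    aligned if input-space alignment is wanted; see :func:`prepare_task`).
    Returns the trained model, the target test pool and the loss history.
    """
    loss_weights = loss_weights or LossWeights()
    train_cfg = train_cfg or TrainConfig()
    method = method or MSA_METHOD
    return _train_one(task, method, loss_weights, train_cfg,
                      train_cfg.seed, inductive=inductive)


def train_baseline(
    task: TransferTask,
    variant: str,
    loss_weights: LossWeights | None = None,
    train_cfg: TrainConfig | None = None,
) -> tuple[MSAModel, list[Trial], dict]:
    """Train one of the comparison baselines.

    ``source_only`` uses only source labels; ``within`` only the target l%
    labels; ``comb`` both; ``truncation_noalign`` matches channels by
    truncation with no adaptation or distillation.  All variants share the
    backbone, optimizer and epoch budget of the aligned runs.
    """
    if variant not in BASELINE_VARIANTS:
        raise ValueError(f"unknown baseline variant {variant!r}")
    if variant in ("within", "comb") and task.scenario == "unsupervised":
        raise ValueError(f"{variant} baseline requires target labels (l > 0)")
    loss_weights = loss_weights or LossWeights()
    train_cfg = train_cfg or TrainConfig()
    method = MethodConfig(
        name=variant,
        use_ea=False,
        use_resizenet=False,
        da="none",
        kd="none",
        use_source=variant != "within",
        use_target_labels=variant != "source_only",
    )
    return _train_one(task, method, loss_weights, train_cfg, train_cfg.seed)


def run_experiment(
    raw_task: TransferTask,
    method: MethodConfig,
    loss_weights: LossWeights | None = None,
    train_cfg: TrainConfig | None = None,
    seed: int | None = None,
) -> tuple[dict[str, float], dict]:
    """Prepare (resample + optional EA), train and evaluate one run.

    Returns (per-subject AUC map, loss history).
    """
    loss_weights = loss_weights or LossWeights()
    train_cfg = train_cfg or TrainConfig()
    seed = train_cfg.seed if seed is None else seed
    task = prepare_task(raw_task, use_ea=method.use_ea)
    model, test_pool, history = _train_one(task, method, loss_weights,
                                           train_cfg, seed)
    return evaluate_auc(model, test_pool), history


def run_repeated_experiment(
    raw_task: TransferTask,
    method: MethodConfig = MSA_METHOD,
    loss_weights: LossWeights | None = None,
    train_cfg: TrainConfig | None = None,
) -> EvalResult:
    """Repeat train+evaluate with consecutive seeds and report the mean and
    standard deviation of the subject-averaged AUC."""
    train_cfg = train_cfg or TrainConfig()
    seeds = [train_cfg.seed + i for i in range(train_cfg.repeats)]
    per_repeat_mean: list[float] = []
    per_subject: dict[str, list[float]] = {}
    for s in seeds:
        aucs, _ = run_experiment(raw_task, method, loss_weights, train_cfg, seed=s)
        per_repeat_mean.append(float(np.mean(list(aucs.values()))))
        for sid, a in aucs.items():
            per_subject.setdefault(sid, []).append(a)
    return EvalResult(
        per_subject_auc={sid: float(np.mean(v)) for sid, v in per_subject.items()},
        mean_auc=float(np.mean(per_repeat_mean)),
        std_auc=float(np.std(per_repeat_mean)),
        seeds=seeds,
        per_repeat_mean=per_repeat_mean,
    )


def ablation_ladder(
    raw_task: TransferTask,
    loss_weights: LossWeights | None = None,
    train_cfg: TrainConfig | None = None,
) -> dict[str, EvalResult]:
    """Run the alignment ladder none -> +EA -> +DA -> full MSA."""
    return {
        m.name: run_repeated_experiment(raw_task, m, loss_weights, train_cfg)
        for m in ABLATION_STEPS
    }
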