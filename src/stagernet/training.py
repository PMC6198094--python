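"""Training loop, subject-wise cross-validation, regularization wiring.

The stager is trained with a masked categorical cross-entropy over the
five scored classes (UNKNOWN-labelled windows carry weight 0) using Adam
(lr 0.001, beta1 0.9, beta2 0.999, eps 1e-8, decay 0 by default).  A
training epoch is a fixed number of batches of shift-augmented sequences;
the recurrent state is reset at the start of every sequence.  Validation
uses whole-recording causal staging, never augmented sequences, and folds
are split across subjects so no subject contributes to both sides.

Demographic personalization noise: per training sequence, one Gaussian
perturbation (sd sigma_age, in years) is added to the age input, and with
probability p_gender the gender code is replaced by 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, masked_cross_entropy
from .architecture import StagerModel, stage_recording
from .config import StagerConfig, TrainConfig
from .core import EegRecording, Hypnogram
from .evaluation import mean_recording_kappa, pooled_kappa
from .sampling import make_batch, stack_batch

Dataset = list[tuple[EegRecording, Hypnogram]]


@dataclass
class FoldSplit:
    """Partition of the subject set into three near-equal groups."""

    groups: list[list[str]]

    def __post_init__(self) -> None:
        sizes = [len(g) for g in self.groups]
        if max(sizes) - min(sizes) > 1:
            raise ValueError("fold group sizes must differ by at most 1")
        flat = [s for g in self.groups for s in g]
        if len(set(flat)) != len(flat):
            raise ValueError("fold groups must be disjoint")

    @property
    def n_folds(self) -> int:
        return len(self.groups)

    def fold(self, k: int) -> tuple[list[str], list[str]]:
        """(training subjects, validation subjects) for fold ``k``."""
        val = list(self.groups[k])
        train = [s for j, g in enumerate(self.groups) if j != k for s in g]
        return train, val


def make_cv_folds(
    subject_ids: list[str], rng: np.random.Generator, n_folds: int = 3
) -> FoldSplit:
    """Random subject-wise partition into ``n_folds`` near-equal groups."""
    ids = list(dict.fromkeys(subject_ids))  # unique, order-preserving
    if len(ids) < n_folds:
        raise ValueError(f"need at least {n_folds} subjects, got {len(ids)}")
    perm = [ids[i] for i in rng.permutation(len(ids))]
    groups = [list(g) for g in np.array_split(perm, n_folds)]
    return FoldSplit(groups=groups)


def perturb_demographics(
    age: float | None,
    gender: int | None,
    sigma_age: float,
    p_gender: float,
    rng: np.random.Generator,
) -> tuple[float | None, int]:
    """One per-sequence noise draw on the demographic inputs."""
    if gender not in (1, -1, None):
        raise ValueError("gender code must be +1 or -1")
    if sigma_age < 0 or not (0.0 <= p_gender <= 1.0):
        raise ValueError("invalid personalization noise settings")
    new_age = age
    if age is not None and sigma_age > 0:
        new_age = age + float(rng.normal(0.0, sigma_age))
    new_gender = 0 if (gender is None or rng.random() < p_gender) else gender
    return new_age, new_gender


def regularization_terms(model: StagerModel) -> tuple[float, dict[str, np.ndarray]]:
    """L1/L2 penalty value and gradients on conv and recurrent kernels.

    Penalties touch kernel weight matrices only, never biases.  The L2
    term is lambda * sum(w^2) (gradient 2*lambda*w).
    """
    cfg = model.config
    loss = 0.0
    grads: dict[str, np.ndarray] = {}
    kernel_groups = []
    conv_keys = [f"conv{i}_W" for i in range(len(cfg.conv_filters))]
    rec_keys = [
        f"{name}_{suffix}"
        for name in model.recurrent_layer_names()
        for suffix in ("Wx", "Wh")
    ]
    kernel_groups.append((conv_keys, cfg.l1_conv, cfg.l2_conv))
    kernel_groups.append((rec_keys, cfg.l1_rec, cfg.l2_rec))
    for keys, l1, l2 in kernel_groups:
        if l1 == 0.0 and l2 == 0.0:
            continue
        for k in keys:
            w = model.params[k]
            loss += l1 * float(np.sum(np.abs(w))) + l2 * float(np.sum(w * w))
            grads[k] = l1 * np.sign(w) + 2.0 * l2 * w
    return loss, grads


@dataclass
class LearningCurves:
    """Per-epoch training loss and whole-recording Kappa scores.

    Kappa entries are NaN for epochs where evaluation was skipped
    (``TrainConfig.eval_every`` > 1).
    """

    train_loss: list[float] = field(default_factory=list)
    train_kappa: list[float] = field(default_factory=list)
    val_kappa: list[float] = field(default_factory=list)


def _dataset_kappa(model: StagerModel, data: Dataset, pooled: bool = True) -> float:
    pairs = []
    for rec, hyp in data:
        pred, _ = stage_recording(model, rec)
        n = min(len(pred), len(hyp))
        pairs.append((Hypnogram(pred.stages[:n]), Hypnogram(hyp.stages[:n])))
    return pooled_kappa(pairs) if pooled else mean_recording_kappa(pairs)


def train_single(
    config: StagerConfig,
    tconfig: TrainConfig,
    train_data: Dataset,
    val_data: Dataset | None = None,
    seed: int | None = None,
) -> tuple[StagerModel, LearningCurves]:
    """Train one model on ``train_data``; log whole-recording Kappa curves."""
    master = tconfig.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    init_ss, sampler_ss, dropout_ss, demo_ss = ss.spawn(4)
    model = StagerModel(config, seed=int(init_ss.generate_state(1)[0] % (2**31)))
    sampler_rng = np.random.default_rng(sampler_ss)
    dropout_rng = np.random.default_rng(dropout_ss)
    demo_rng = np.random.default_rng(demo_ss)
    opt = Adam(
        model.params,
        lr=tconfig.learning_rate,
        beta1=tconfig.beta1,
        beta2=tconfig.beta2,
        eps=tconfig.epsilon,
        decay=tconfig.decay,
    )
    use_dropout = config.dropout_forward > 0 or config.dropout_recurrent > 0
    curves = LearningCurves()
    for epoch in range(tconfig.n_epochs):
        epoch_loss = 0.0
        for _ in range(tconfig.batches_per_epoch):
            batch = make_batch(
                train_data,
                tconfig.batch_size,
                tconfig.seq_len_windows,
                sampler_rng,
                augment=tconfig.shift_augmentation,
            )
            X, labels, mask, demo_raw = stack_batch(batch)
            demo = np.zeros((len(batch), 2))
            for i, (age, gender) in enumerate(demo_raw):
                a, g = perturb_demographics(
                    age, gender, tconfig.sigma_age, tconfig.p_gender_mask, demo_rng
                )
                demo[i] = model.make_demo(a, g)
            probs, cache = model.forward_sequence(
                X,
                demo,
                dropout_rng=dropout_rng if use_dropout else None,
                return_cache=True,
            )
            loss, dlogits = masked_cross_entropy(probs, labels, mask)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training aborted: non-finite loss at epoch {epoch}"
                )
            grads = model.backward_sequence(dlogits, cache)
            pen_loss, pen_grads = regularization_terms(model)
            loss += pen_loss
            for k, g in pen_grads.items():
                grads[k] = grads.get(k, 0.0) + g
            if tconfig.grad_clip is not None:
                norm = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
                if norm > tconfig.grad_clip:
                    scale = tconfig.grad_clip / norm
                    grads = {k: g * scale for k, g in grads.items()}
            opt.step(model.params, grads)
            epoch_loss += loss
        curves.train_loss.append(epoch_loss / tconfig.batches_per_epoch)
        evaluate_now = (epoch + 1) % tconfig.eval_every == 0 or epoch == tconfig.n_epochs - 1
        curves.train_kappa.append(
            _dataset_kappa(model, train_data) if evaluate_now else float("nan")
        )
        curves.val_kappa.append(
            _dataset_kappa(model, val_data)
            if (evaluate_now and val_data)
            else float("nan")
        )
    return model, curves


def train_stager(
    config: StagerConfig,
    tconfig: TrainConfig,
    dataset: Dataset,
    folds: FoldSplit | None = None,
    fold_indices: list[int] | None = None,
) -> list[tuple[StagerModel, LearningCurves]]:
    """Subject-wise cross-validated training; one model per requested fold."""
    rng = np.random.default_rng(tconfig.seed)
    if folds is None:
        folds = make_cv_folds([rec.subject_id for rec, _ in dataset], rng)
    results = []
    for k in fold_indices if fold_indices is not None else range(folds.n_folds):
        train_ids, val_ids = folds.fold(k)
        train_data = [dv for dv in dataset if dv[0].subject_id in train_ids]
        val_data = [dv for dv in dataset if dv[0].subject_id in val_ids]
        audit_fold_isolation(train_data, val_data)
        results.append(
            train_single(config, tconfig, train_data, val_data, seed=tconfig.seed + k)
        )
    return results


def audit_fold_isolation(train_data: Dataset, val_data: Dataset) -> None:
    """Assert no subject appears on both sides of a fold."""
    train_ids = {rec.subject_id for rec, _ in train_data}
    val_ids = {rec.subject_id for rec, _ in val_data}
    overlap = train_ids & val_ids
    if overlap:
        raise ValueError(f"subjects in both train and validation: {sorted(overlap)}")
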