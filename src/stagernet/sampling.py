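"""Random time-shift augmentation sampler and training-batch construction.

Training sequences are runs of consecutive, non-overlapping 3000-sample
windows whose starting sample is drawn uniformly from anywhere inside a
recording — not necessarily on the 30-s annotation grid.  Each window's
target label is the annotated stage of the epoch containing the window's
central sample.  Because any of the 3000 within-epoch offsets is
admissible, this augmentation virtually multiplies the number of distinct
label/window alignments by 3000.

Windows whose nearest annotation is UNKNOWN stay in the sequence (the
recurrent state needs the temporal continuity) but carry loss weight 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import EegRecording, Hypnogram, SleepStage, WINDOW_SAMPLES


class SamplingError(ValueError):
    """Recording/dataset cannot supply the requested sequence."""


@dataclass
class TrainingSequence:
    """One augmented training sequence drawn from a single recording."""

    windows: np.ndarray  # (seq_len, 3000)
    labels: np.ndarray  # (seq_len,) int stage codes
    label_mask: np.ndarray  # (seq_len,) 1.0 scored / 0.0 UNKNOWN
    age: float | None
    gender: int | None
    start_sample: int


def window_center_epoch(start_sample: int, window_index: int) -> int:
    """Annotation epoch whose span contains the window's central sample.

    The center of the 3000-sample window is defined at offset +1500
    (right-of-center for even length); a center landing exactly on an
    epoch boundary belongs to the later epoch.
    """
    center = start_sample + WINDOW_SAMPLES * window_index + WINDOW_SAMPLES // 2
    return center // WINDOW_SAMPLES


def draw_sequence(
    recording: EegRecording,
    hypnogram: Hypnogram,
    seq_len: int,
    rng: np.random.Generator,
    start_sample: int | None = None,
) -> TrainingSequence:
    """Draw one shift-augmented sequence of ``seq_len`` windows.

    The start sample is uniform on [0, len - seq_len*3000]; pass
    ``start_sample`` to pin it (used by tests and by non-augmented
    training, which pins it to 0).
    """
    span = seq_len * WINDOW_SAMPLES
    n = len(recording.samples)
    if n < span:
        raise SamplingError(
            f"recording of {n} samples cannot hold {seq_len} windows"
        )
    if start_sample is None:
        start_sample = int(rng.integers(0, n - span + 1))
    elif not (0 <= start_sample <= n - span):
        raise SamplingError(f"start sample {start_sample} out of range")
    windows = recording.samples[start_sample : start_sample + span].reshape(
        seq_len, WINDOW_SAMPLES
    )
    codes = hypnogram.codes()
    labels = np.empty(seq_len, dtype=np.int64)
    for i in range(seq_len):
        e = window_center_epoch(start_sample, i)
        labels[i] = codes[e] if e < len(codes) else int(SleepStage.UNKNOWN)
    mask = (labels != int(SleepStage.UNKNOWN)).astype(np.float64)
    return TrainingSequence(
        windows=windows,
        labels=labels,
        label_mask=mask,
        age=recording.age,
        gender=recording.gender,
        start_sample=start_sample,
    )


def admissible_starts(recording: EegRecording, seq_len: int) -> int:
    """Number of distinct start samples a recording admits."""
    return max(0, len(recording.samples) - seq_len * WINDOW_SAMPLES + 1)


def make_batch(
    dataset: list[tuple[EegRecording, Hypnogram]],
    batch_size: int,
    seq_len: int,
    rng: np.random.Generator,
    augment: bool = True,
) -> list[TrainingSequence]:
    """Draw a batch of independent sequences, uniform over recordings.

    Sampling is with replacement: every sequence independently picks a
    (subject, recording) pair uniformly, then a start sample within it.
    """
    if not dataset:
        raise SamplingError("empty dataset")
    for rec, _ in dataset:
        if admissible_starts(rec, seq_len) < 1:
            raise SamplingError(
                f"recording {rec.subject_id!r} too short for seq_len={seq_len}"
            )
    batch = []
    for _ in range(batch_size):
        rec, hyp = dataset[int(rng.integers(0, len(dataset)))]
        start = None if augment else 0
        batch.append(draw_sequence(rec, hyp, seq_len, rng, start_sample=start))
    return batch


def stack_batch(batch: list[TrainingSequence]):
    """Batch list -> (X (B,T,3000), labels (B,T), mask (B,T), demo list)."""
    X = np.stack([s.windows for s in batch])
    labels = np.stack([s.labels for s in batch])
    mask = np.stack([s.label_mask for s in batch])
    demo_raw = [(s.age, s.gender) for s in batch]
    return X, labels, mask, demo_raw
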