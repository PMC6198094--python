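"""Core domain types for single-channel EEG sleep staging.

Sleep staging assigns one of five stages (wake, REM, N1, N2, N3) to every
consecutive 30-second epoch of an overnight EEG recording; epochs with poor
signal quality carry the sixth, non-classifier label UNKNOWN.  The types here
are shared by every other module: the stage code, the sampled recording with
its demographics, the per-epoch hypnogram, and the agreement report.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

EPOCH_SECONDS = 30
#: Model-ready sampling rate after preprocessing (Hz).
MODEL_RATE = 100
#: Samples per 30-s scoring window at the model rate.
WINDOW_SAMPLES = EPOCH_SECONDS * MODEL_RATE


class SleepStage(enum.IntEnum):
    """Six-valued stage code; the first five are the classifier classes.

    Integer values follow the fixed class ordering used for all probability
    vectors and confusion matrices (N3 first).  UNKNOWN marks unscorable
    epochs and is never a classifier output.
    """

    N3 = 0
    N2 = 1
    N1 = 2
    REM = 3
    WAKE = 4
    UNKNOWN = 5


#: Fixed ordering of the five classifier classes for vectors and matrices.
CLASS_ORDER: tuple[SleepStage, ...] = (
    SleepStage.N3,
    SleepStage.N2,
    SleepStage.N1,
    SleepStage.REM,
    SleepStage.WAKE,
)
N_CLASSES = len(CLASS_ORDER)

#: Text tokens accepted in hypnogram CSV files.  R&K stages S3 and S4 are
#: folded into the single class N3.
STAGE_TOKENS: dict[str, SleepStage] = {
    "W": SleepStage.WAKE,
    "N1": SleepStage.N1,
    "N2": SleepStage.N2,
    "N3": SleepStage.N3,
    "R": SleepStage.REM,
    "U": SleepStage.UNKNOWN,
    "S3": SleepStage.N3,
    "S4": SleepStage.N3,
}

#: Canonical token written for each stage (round-trip uses these).
STAGE_TO_TOKEN: dict[SleepStage, str] = {
    SleepStage.WAKE: "W",
    SleepStage.N1: "N1",
    SleepStage.N2: "N2",
    SleepStage.N3: "N3",
    SleepStage.REM: "R",
    SleepStage.UNKNOWN: "U",
}


@dataclass
class EegRecording:
    """A sampled single-channel EEG amplitude series in microvolts."""

    samples: np.ndarray
    rate: float
    subject_id: str = ""
    age: float | None = None
    gender: int | None = None  # +1 men, -1 women
    channel_label: str = "FPz-M2"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not self.rate > 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.gender not in (None, 1, -1):
            raise ValueError("gender code must be +1, -1 or None")

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return len(self.samples) / self.rate

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class Hypnogram:
    """Per-epoch stage sequence aligned to the start of a recording."""

    stages: list[SleepStage]
    epoch_seconds: int = EPOCH_SECONDS

    def __post_init__(self) -> None:
        self.stages = [SleepStage(s) for s in self.stages]
        if self.epoch_seconds != EPOCH_SECONDS:
            raise ValueError("epochs are fixed at 30 s")

    def __len__(self) -> int:
        return len(self.stages)

    def __getitem__(self, i):
        return self.stages[i]

    def __iter__(self):
        return iter(self.stages)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Hypnogram)
            and self.stages == other.stages
            and self.epoch_seconds == other.epoch_seconds
        )

    def codes(self) -> np.ndarray:
        """Integer stage codes as an array (N3=0 ... UNKNOWN=5)."""
        return np.array([int(s) for s in self.stages], dtype=np.int64)

    def scored_mask(self) -> np.ndarray:
        """Boolean mask of epochs with a proper (non-UNKNOWN) stage."""
        return self.codes() != int(SleepStage.UNKNOWN)

    def stage_fractions(self) -> dict[SleepStage, float]:
        """Fraction of epochs per stage code, including UNKNOWN."""
        codes = self.codes()
        n = len(codes)
        return {s: float(np.mean(codes == int(s))) for s in SleepStage}


@dataclass
class EvaluationReport:
    """Hypnogram-agreement summary: Kappa, confusion, per-stage scores.

    ``confusion`` is row-normalized with rows = true stage in the fixed class
    order (N3, N2, N1, REM, WAKE); rows without support are all-zero and
    listed in ``zero_support_rows``.
    """

    kappa: float
    confusion: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    n_scored_epochs: int
    zero_support_rows: list[int] = field(default_factory=list)

    def per_stage(self) -> dict[str, dict[str, float]]:
        out = {}
        for i, stage in enumerate(CLASS_ORDER):
            out[stage.name] = {
                "precision": float(self.precision[i]),
                "recall": float(self.recall[i]),
                "f1": float(self.f1[i]),
            }
        return out

    def to_dict(self) -> dict:
        return {
            "kappa": float(self.kappa),
            "confusion": self.confusion.tolist(),
            "class_order": [s.name for s in CLASS_ORDER],
            "per_stage": self.per_stage(),
            "n_scored_epochs": int(self.n_scored_epochs),
            "zero_support_rows": list(self.zero_support_rows),
        }
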