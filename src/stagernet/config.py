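"""Architecture and training hyperparameter sets.

``StagerConfig()`` with no arguments reproduces the baseline stager: three
convolutional layers with 8/16/32 filters (kernel 8, stride 1, no padding,
max-pool 8, ReLU) feeding a 2-layer, 64-unit LSTM stack and a 5-unit
recurrent softmax output, demographics disabled, no regularization.
``TrainConfig()`` reproduces the baseline training protocol (Adam with
lr 0.001, 128-sequence batches of 128 windows, 16 batches per epoch,
512 epochs).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class StagerConfig:
    """Full architecture description of the CONV/recurrent stager."""

    n_conv_layers: int = 3
    conv_filters: tuple[int, ...] = (8, 16, 32)
    kernel_width: int = 8
    stride: int = 1
    pool_factor: int = 8
    conv_activation: str = "relu"  # or "leaky_relu"
    recurrent_kind: str = "lstm"  # or "gru"
    n_recurrent_layers: int = 2
    units_per_layer: int = 64
    output_classes: int = 5
    use_age: bool = False
    use_gender: bool = False
    l1_conv: float = 0.0
    l2_conv: float = 0.0
    l1_rec: float = 0.0
    l2_rec: float = 0.0
    dropout_forward: float = 0.0
    dropout_recurrent: float = 0.0
    # Fixed numerical conventions (not architecture axes):
    input_scale: float = 0.05  # microvolts -> O(1) network input
    leaky_slope: float = 0.01
    window_samples: int = 3000

    def __post_init__(self) -> None:
        self.conv_filters = tuple(int(f) for f in self.conv_filters)
        if self.n_conv_layers != len(self.conv_filters):
            # allow shorthand: truncate/extend default ladder
            if self.n_conv_layers < len(self.conv_filters):
                self.conv_filters = self.conv_filters[: self.n_conv_layers]
            else:
                raise ValueError(
                    "conv_filters must list one filter count per conv layer"
                )
        if self.conv_activation not in ("relu", "leaky_relu"):
            raise ValueError(f"unknown conv activation {self.conv_activation!r}")
        if self.recurrent_kind not in ("lstm", "gru"):
            raise ValueError(f"unknown recurrent kind {self.recurrent_kind!r}")
        if self.stride != 1:
            raise ValueError("only stride 1 is supported")
        for name in ("l1_conv", "l2_conv", "l1_rec", "l2_rec"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("dropout_forward", "dropout_recurrent"):
            p = getattr(self, name)
            if not (0.0 <= p < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")
        if self.output_classes != 5:
            raise ValueError("the stager has exactly 5 output classes")

    @property
    def demographic_width(self) -> int:
        """Demographic input vector width; always present, clamped to 0
        when the use_* flags are off."""
        return 2

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["conv_filters"] = list(self.conv_filters)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StagerConfig":
        return cls(**d)


@dataclass
class TrainConfig:
    """Training protocol hyperparameters (Adam + sequence sampling)."""

    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    decay: float = 0.0
    batch_size: int = 128
    seq_len_windows: int = 128
    batches_per_epoch: int = 16
    n_epochs: int = 512
    sigma_age: float = 0.0
    p_gender_mask: float = 0.0
    seed: int = 0
    shift_augmentation: bool = True
    eval_every: int = 1
    grad_clip: float | None = None

    def __post_init__(self) -> None:
        for name in ("batch_size", "seq_len_windows", "batches_per_epoch"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_epochs < 0:
            raise ValueError("n_epochs must be >= 0")
        if not (0.0 <= self.p_gender_mask <= 1.0):
            raise ValueError("p_gender_mask must be in [0, 1]")
        if self.sigma_age < 0:
            raise ValueError("sigma_age must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**d)


def save_config(obj: StagerConfig | TrainConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj.to_dict(), fh, sort_keys=True)


def load_stager_config(path: str | Path) -> StagerConfig:
    with open(path) as fh:
        return StagerConfig.from_dict(yaml.safe_load(fh))


def load_train_config(path: str | Path) -> TrainConfig:
    with open(path) as fh:
        return TrainConfig.from_dict(yaml.safe_load(fh))


def load_demographics(path: str | Path) -> dict[str, dict]:
    """Sidecar demographics keyed by subject_id: {id: {age, gender}}."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    for sid, entry in data.items():
        if entry.get("gender") not in (1, -1, None):
            raise ValueError(f"subject {sid}: gender code must be +1 or -1")
    return data
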