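"""The configurable CONV/recurrent sleep stager.

The model maps a stream of 30-s, 3000-sample EEG windows to per-window
stage probabilities over (N3, N2, N1, REM, WAKE).  Each window passes
through a stack of valid-mode convolutions (ReLU or leaky-ReLU, max-pool)
acting as a local spectral feature extractor; the flattened features are
concatenated with a 2-element demographic vector (age, gender; clamped to
zero when disabled) and fed to a stack of LSTM (or GRU) layers that carry
state across the night, ending in a small 5-unit recurrent layer whose
outputs pass through a softmax.  Inference is strictly causal: the
probability for window t depends only on windows 0..t.

With the default configuration the conv stack outputs have shapes
(374, 8), (45, 16) and (4, 32); the flattened feature width is 128 and the
recurrent input width 130.

Per-layer trainable parameter counts: a conv layer holds
``filters * kernel_width * in_channels + filters`` values, an LSTM layer
``4 * units * (input + units + 1)`` and a GRU layer the same with factor 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _nn
from .core import CLASS_ORDER, EegRecording, Hypnogram, MODEL_RATE, N_CLASSES, SleepStage
from .config import StagerConfig
from .preprocessing import segment_into_windows


class ConfigurationError(ValueError):
    """Architecture cannot be realized (e.g. a layer collapses to length 0)."""


def conv_stack_shapes(config: StagerConfig, input_len: int | None = None):
    """Per-layer (time_steps, channels) after conv+pool for each conv layer."""
    t = config.window_samples if input_len is None else input_len
    shapes = []
    for f in config.conv_filters:
        t_conv = t - config.kernel_width + 1
        if t_conv < 1:
            raise ConfigurationError(
                f"time length {t} shorter than kernel {config.kernel_width}"
            )
        t = t_conv // config.pool_factor
        if t < 1:
            raise ConfigurationError("pooling collapsed the time axis to zero")
        shapes.append((t, f))
    return shapes


def flattened_feature_width(config: StagerConfig, input_len: int | None = None) -> int:
    shapes = conv_stack_shapes(config, input_len)
    if not shapes:
        return config.window_samples if input_len is None else input_len
    t, f = shapes[-1]
    return t * f


def _rec_factor(kind: str) -> int:
    return 4 if kind == "lstm" else 3


def count_parameters(config: StagerConfig) -> dict:
    """Per-layer and total trainable parameter counts for a configuration."""
    conv_counts = []
    c_in = 1
    for f in config.conv_filters:
        conv_counts.append(f * config.kernel_width * c_in + f)
        c_in = f
    g = _rec_factor(config.recurrent_kind)
    rec_counts = []
    width = flattened_feature_width(config) + config.demographic_width
    for _ in range(config.n_recurrent_layers):
        u = config.units_per_layer
        rec_counts.append(g * u * (width + u + 1))
        width = u
    out_count = g * config.output_classes * (width + config.output_classes + 1)
    return {
        "conv": conv_counts,
        "recurrent": rec_counts,
        "output": out_count,
        "total": sum(conv_counts) + sum(rec_counts) + out_count,
    }


@dataclass
class StreamState:
    """Recurrent state carried across windows during streaming inference."""

    hidden: list[np.ndarray]
    cell: list[np.ndarray | None]


class StagerModel:
    """Realized weight containers plus forward/backward computation."""

    def __init__(self, config: StagerConfig, seed: int = 0):
        self.config = config
        self.params: dict[str, np.ndarray] = {}
        self._init_params(np.random.default_rng(seed))

    # -- construction -----------------------------------------------------

    def _init_params(self, rng) -> None:
        cfg = self.config
        c_in = 1
        for i, f in enumerate(cfg.conv_filters):
            fan_in = cfg.kernel_width * c_in
            self.params[f"conv{i}_W"] = _nn.glorot_uniform(
                rng, (f, cfg.kernel_width, c_in), fan_in, f
            )
            self.params[f"conv{i}_b"] = np.zeros(f)
            c_in = f
        g = _rec_factor(cfg.recurrent_kind)
        width = flattened_feature_width(cfg) + cfg.demographic_width
        layer_dims = [(width, cfg.units_per_layer)]
        for _ in range(cfg.n_recurrent_layers - 1):
            layer_dims.append((cfg.units_per_layer, cfg.units_per_layer))
        last = cfg.units_per_layer if cfg.n_recurrent_layers else width
        layer_dims.append((last, cfg.output_classes))  # output layer
        for li, (d, u) in enumerate(layer_dims):
            name = "out" if li == len(layer_dims) - 1 else f"rec{li}"
            self.params[f"{name}_Wx"] = _nn.glorot_uniform(rng, (d, g * u), d, u)
            self.params[f"{name}_Wh"] = _nn.glorot_uniform(rng, (u, g * u), u, u)
            b = np.zeros(g * u)
            if cfg.recurrent_kind == "lstm":
                b[u : 2 * u] = 1.0  # forget-gate bias: remember by default
            self.params[f"{name}_b"] = b
        self._layer_dims = layer_dims

    @property
    def n_parameters(self) -> int:
        return sum(int(np.prod(v.shape)) for v in self.params.values())

    def recurrent_layer_names(self) -> list[str]:
        return [f"rec{i}" for i in range(self.config.n_recurrent_layers)] + ["out"]

    # -- demographics ------------------------------------------------------

    def make_demo(self, age: float | None, gender: int | float | None) -> np.ndarray:
        """Demographic input vector; entries clamped to 0 when disabled.

        Age is fed in units of centuries (years/100) so all network inputs
        are O(1); the gender code is +1/-1/0.
        """
        cfg = self.config
        a = (age or 0.0) / 100.0 if cfg.use_age else 0.0
        g = float(gender or 0.0) if cfg.use_gender else 0.0
        return np.array([a, g])

    # -- conv stack --------------------------------------------------------

    def conv_features(self, windows: np.ndarray, return_cache: bool = False):
        """Run the conv stack on (N, 3000) windows -> (N, t_last, ch_last)."""
        cfg = self.config
        x = np.asarray(windows, dtype=np.float64) * cfg.input_scale
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != cfg.window_samples:
            raise ValueError(
                f"windows must have {cfg.window_samples} samples, got {x.shape[1]}"
            )
        x = x[:, :, None]
        cache = []
        for i in range(len(cfg.conv_filters)):
            pre = _nn.conv1d_forward(x, self.params[f"conv{i}_W"], self.params[f"conv{i}_b"])
            act = _nn.act_forward(pre, cfg.conv_activation, cfg.leaky_slope)
            pooled, idx = _nn.maxpool_forward(act, cfg.pool_factor)
            cache.append((x, pre, act.shape, idx))
            x = pooled
        return (x, cache) if return_cache else x

    def _conv_backward(self, dOut, cache):
        cfg = self.config
        grads = {}
        dx = dOut
        for i in range(len(cfg.conv_filters) - 1, -1, -1):
            x, pre, act_shape, idx = cache[i]
            dact = _nn.maxpool_backward(act_shape, cfg.pool_factor, idx, dx)
            dpre = _nn.act_backward(pre, dact, cfg.conv_activation, cfg.leaky_slope)
            dx, dW, db = _nn.conv1d_backward(x, self.params[f"conv{i}_W"], dpre)
            grads[f"conv{i}_W"] = dW
            grads[f"conv{i}_b"] = db
        return grads

    # -- full sequence forward / backward ---------------------------------

    def _make_masks(self, batch: int, rng):
        """Variational dropout masks, one per sequence, fixed over time."""
        cfg = self.config
        masks = []
        for d, u in self._layer_dims:
            mx = mh = None
            if rng is not None and cfg.dropout_forward > 0:
                keep = 1.0 - cfg.dropout_forward
                mx = (rng.random((batch, d)) < keep) / keep
            if rng is not None and cfg.dropout_recurrent > 0:
                keep = 1.0 - cfg.dropout_recurrent
                mh = (rng.random((batch, u)) < keep) / keep
            masks.append((mx, mh))
        return masks

    def forward_sequence(
        self,
        X: np.ndarray,
        demo: np.ndarray | None = None,
        dropout_rng: np.random.Generator | None = None,
        return_cache: bool = False,
    ):
        """Probabilities for a batch of sequences.

        X: (B, T, 3000); demo: (B, 2) or None (zeros).  The recurrent state
        starts at zero for every sequence.  Returns (B, T, 5) probabilities
        (and a cache for the backward pass when requested).
        """
        cfg = self.config
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2:
            X = X[None, :, :]
        B, T, W = X.shape
        feats, conv_cache = self.conv_features(X.reshape(B * T, W), return_cache=True)
        feat_width = feats.shape[1] * feats.shape[2]
        feats = feats.reshape(B, T, feat_width)
        if demo is None:
            demo = np.zeros((B, 2))
        demo = np.broadcast_to(np.asarray(demo, dtype=np.float64), (B, 2))
        h = np.concatenate([feats, np.repeat(demo[:, None, :], T, axis=1)], axis=2)
        masks = self._make_masks(B, dropout_rng)
        rec_caches = []
        for li, name in enumerate(self.recurrent_layer_names()):
            u = self._layer_dims[li][1]
            mx, mh = masks[li]
            h0 = np.zeros((B, u))
            if cfg.recurrent_kind == "lstm":
                c0 = np.zeros((B, u))
                h, _, cache = _nn.lstm_forward(
                    h, self.params[f"{name}_Wx"], self.params[f"{name}_Wh"],
                    self.params[f"{name}_b"], h0, c0, mx, mh,
                )
            else:
                h, _, cache = _nn.gru_forward(
                    h, self.params[f"{name}_Wx"], self.params[f"{name}_Wh"],
                    self.params[f"{name}_b"], h0, mx, mh,
                )
            rec_caches.append(cache)
        probs = _nn.softmax(h, axis=-1)
        if not return_cache:
            return probs
        full_cache = (conv_cache, rec_caches, (B, T, W, feat_width))
        return probs, full_cache

    def backward_sequence(self, dlogits: np.ndarray, cache) -> dict[str, np.ndarray]:
        """Gradients of the loss w.r.t. all parameters.

        ``dlogits`` is the gradient w.r.t. the output layer's pre-softmax
        values (as returned by the masked cross-entropy helper).
        """
        conv_cache, rec_caches, (B, T, W, feat_width) = cache
        grads: dict[str, np.ndarray] = {}
        dh = dlogits
        names = self.recurrent_layer_names()
        for li in range(len(names) - 1, -1, -1):
            name = names[li]
            if self.config.recurrent_kind == "lstm":
                dh, dWx, dWh, db = _nn.lstm_backward(
                    dh, self.params[f"{name}_Wx"], self.params[f"{name}_Wh"],
                    rec_caches[li],
                )
            else:
                dh, dWx, dWh, db = _nn.gru_backward(
                    dh, self.params[f"{name}_Wx"], self.params[f"{name}_Wh"],
                    rec_caches[li],
                )
            grads[f"{name}_Wx"] = dWx
            grads[f"{name}_Wh"] = dWh
            grads[f"{name}_b"] = db
        dfeats = dh[:, :, :feat_width]
        n_conv = len(self.config.conv_filters)
        if n_conv:
            last_shape = conv_cache[-1][2]  # activation shape pre-pool
            t_last = last_shape[1] // self.config.pool_factor
            ch_last = last_shape[2]
            dconv_out = dfeats.reshape(B * T, t_last, ch_last)
            grads.update(self._conv_backward(dconv_out, conv_cache))
        return grads

    # -- streaming inference ----------------------------------------------

    def init_state(self) -> StreamState:
        """Zero recurrent state for the start of a recording."""
        hidden, cell = [], []
        for _, u in self._layer_dims:
            hidden.append(np.zeros(u))
            cell.append(np.zeros(u) if self.config.recurrent_kind == "lstm" else None)
        return StreamState(hidden=hidden, cell=cell)

    def step(
        self,
        window: np.ndarray,
        age: float | None = None,
        gender: int | None = None,
        state: StreamState | None = None,
    ) -> tuple[np.ndarray, StreamState]:
        """Causal single-window inference: (5,) probabilities + new state."""
        window = np.asarray(window, dtype=np.float64)
        if window.shape != (self.config.window_samples,):
            raise ValueError(
                f"window must hold exactly {self.config.window_samples} samples"
            )
        if state is None:
            state = self.init_state()
        feats = self.conv_features(window[None, :]).reshape(-1)
        x = np.concatenate([feats, self.make_demo(age, gender)])
        new_h, new_c = [], []
        for li, name in enumerate(self.recurrent_layer_names()):
            Wx = self.params[f"{name}_Wx"]
            Wh = self.params[f"{name}_Wh"]
            b = self.params[f"{name}_b"]
            if self.config.recurrent_kind == "lstm":
                h, c = _nn.lstm_step(x, state.hidden[li], state.cell[li], Wx, Wh, b)
                new_c.append(c)
            else:
                h = _nn.gru_step(x, state.hidden[li], Wx, Wh, b)
                new_c.append(None)
            new_h.append(h)
            x = h
        probs = _nn.softmax(x)
        return probs, StreamState(hidden=new_h, cell=new_c)


def hard_decision(probs: np.ndarray) -> SleepStage:
    """Argmax stage; ties break toward the first class in the fixed order."""
    probs = np.asarray(probs, dtype=np.float64)
    if probs.shape != (N_CLASSES,) or not np.all(np.isfinite(probs)):
        raise ValueError("probs must be a finite 5-vector")
    return CLASS_ORDER[int(np.argmax(probs))]


def stage_recording(
    model: StagerModel,
    recording: EegRecording,
    age: float | None = None,
    gender: int | None = None,
) -> tuple[Hypnogram, np.ndarray]:
    """Stage a whole preprocessed recording causally from sample 0.

    Windows start at the first sample so decision boundaries coincide with
    the manual 30-s scoring grid; the recurrent state is zero-initialized
    once and carried across the entire night.  Returns the hard-decision
    hypnogram and the (n_epochs, 5) probability matrix.
    """
    if recording.rate != MODEL_RATE:
        raise ValueError("stage_recording expects a preprocessed 100 Hz recording")
    windows = segment_into_windows(recording)
    if len(windows) == 0:
        raise ValueError("recording shorter than one 30-s window")
    demo = model.make_demo(
        age if age is not None else recording.age,
        gender if gender is not None else recording.gender,
    )
    probs = model.forward_sequence(windows[None, :, :], demo[None, :])[0]
    stages = [hard_decision(p) for p in probs]
    return Hypnogram(stages=stages), probs
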