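"""Conv-feature frequency probing and the FFT logistic-regression baseline.

``probe_conv_features`` characterizes what the convolutional stack has
learned by driving it with pure sinusoids (default 0.5-50 Hz in 0.5 Hz
steps, 50 uV peak-to-peak — the typical sleep-EEG amplitude) and recording
the mean absolute activation of each flattened conv output.  Trained
stagers develop features tuned to the classic EEG bands.

The comparison baseline is a multinomial logistic regression over the
complete per-epoch spectrum: magnitude and phase of the real FFT of each
3000-sample window (3000 independent values, lossless up to sign
conventions), classified epoch-by-epoch with no temporal context.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .architecture import StagerModel, conv_stack_shapes
from .core import (
    CLASS_ORDER,
    EegRecording,
    EvaluationReport,
    Hypnogram,
    MODEL_RATE,
    SleepStage,
    WINDOW_SAMPLES,
)
from .bands import PARTITION
from .evaluation import evaluate
from .preprocessing import segment_into_windows


@dataclass
class FeatureResponseMap:
    """Activation magnitude of each conv feature vs. probe frequency."""

    response: np.ndarray  # (n_features, n_frequencies), all >= 0
    frequencies: np.ndarray  # Hz


def probe_conv_features(
    model: StagerModel,
    f_start: float = 0.5,
    f_stop: float = 50.0,
    f_step: float = 0.5,
    amplitude_pp: float = 50.0,
    n_phases: int = 8,
) -> FeatureResponseMap:
    """Sinusoidal frequency response of the flattened conv features.

    For each probe frequency a 3000-sample sinusoid at 100 Hz is passed
    through the conv stack only; the (time x channels) output is flattened
    and reduced to one value per flattened feature by averaging absolute
    activations over ``n_phases`` uniformly spaced input phases (the input
    is stationary, so the few surviving time positions carry the same
    statistics).
    """
    if f_step <= 0 or f_stop < f_start:
        raise ValueError("need f_step > 0 and f_stop >= f_start")
    freqs = np.arange(f_start, f_stop + f_step / 2, f_step)
    if len(freqs) == 0:
        raise ValueError("empty probe frequency range")
    amp = amplitude_pp / 2.0
    t = np.arange(WINDOW_SAMPLES) / MODEL_RATE
    phases = np.arange(n_phases) * (2.0 * np.pi / n_phases)
    n_feat = int(np.prod(conv_stack_shapes(model.config)[-1]))
    response = np.empty((n_feat, len(freqs)))
    for j, f in enumerate(freqs):
        windows = amp * np.sin(2.0 * np.pi * f * t[None, :] + phases[:, None])
        out = np.abs(model.conv_features(windows))  # (n_phases, time, ch)
        # one value per flattened (time, ch) feature: |activation| averaged
        # over input phases, flattened row-major to match the model order
        response[:, j] = out.mean(axis=0).reshape(-1)
    return FeatureResponseMap(response=response, frequencies=freqs)


def band_selectivity(fmap: FeatureResponseMap):
    """Dominant-band label and selectivity ratio per conv feature.

    The dominant band is the one containing the feature's peak response;
    the selectivity ratio is the mean response inside that band divided by
    the overall mean.  All-zero features are labelled "flat".
    """
    labels: list[str] = []
    ratios = np.zeros(fmap.response.shape[0])
    for i, row in enumerate(fmap.response):
        overall = row.mean()
        if overall <= 0.0:
            labels.append("flat")
            ratios[i] = 0.0
            continue
        peak_f = fmap.frequencies[int(np.argmax(row))]
        name = PARTITION[-1][0]
        for band, lo, hi in PARTITION:
            if lo <= peak_f < hi or (band == PARTITION[-1][0] and peak_f >= hi):
                name = band
                break
        lo, hi = next((l, h) for b, l, h in PARTITION if b == name)
        in_band = (fmap.frequencies >= lo) & (fmap.frequencies < hi)
        labels.append(name)
        ratios[i] = row[in_band].mean() / overall
    return labels, ratios


# ---------------------------------------------------------------------------
# FFT features + logistic-regression baseline
# ---------------------------------------------------------------------------


def fft_features(window: np.ndarray) -> np.ndarray:
    """Complete spectral description of one 3000-sample window.

    Layout: [DC real amplitude, Nyquist real amplitude,
    |X_1| ... |X_1499|, angle(X_1) ... angle(X_1499)] — 3000 real values
    that determine the window exactly (DC and Nyquist bins of a real
    signal are real-valued and stored signed).  Zero-magnitude bins get
    phase 0.
    """
    window = np.asarray(window, dtype=np.float64)
    if window.shape != (WINDOW_SAMPLES,):
        raise ValueError(f"window must hold exactly {WINDOW_SAMPLES} samples")
    spec = np.fft.rfft(window)
    mid = spec[1:-1]
    mags = np.abs(mid)
    phases = np.where(mags > 0, np.angle(mid), 0.0)
    return np.concatenate(([spec[0].real, spec[-1].real], mags, phases))


def fft_reconstruct(features: np.ndarray) -> np.ndarray:
    """Invert ``fft_features`` back to the 3000-sample window."""
    features = np.asarray(features, dtype=np.float64)
    n_mid = WINDOW_SAMPLES // 2 - 1
    dc, nyq = features[0], features[1]
    mags = features[2 : 2 + n_mid]
    phases = features[2 + n_mid :]
    spec = np.empty(WINDOW_SAMPLES // 2 + 1, dtype=np.complex128)
    spec[0] = dc
    spec[-1] = nyq
    spec[1:-1] = mags * np.exp(1j * phases)
    return np.fft.irfft(spec, n=WINDOW_SAMPLES)


@dataclass
class LogregBaseline:
    """Fitted per-epoch FFT-feature multinomial logistic regression."""

    scaler: StandardScaler
    clf: LogisticRegression

    @property
    def n_coefficients(self) -> int:
        return int(self.clf.coef_.size + self.clf.intercept_.size)

    def predict_recording(self, recording: EegRecording) -> Hypnogram:
        windows = segment_into_windows(recording)
        X = np.stack([fft_features(w) for w in windows])
        codes = self.clf.predict(self.scaler.transform(X))
        return Hypnogram(stages=[SleepStage(int(c)) for c in codes])


def _epoch_features_labels(dataset):
    X, y = [], []
    for rec, hyp in dataset:
        windows = segment_into_windows(rec)
        codes = hyp.codes()
        n = min(len(windows), len(codes))
        for i in range(n):
            if codes[i] == int(SleepStage.UNKNOWN):
                continue
            X.append(fft_features(windows[i]))
            y.append(codes[i])
    return np.stack(X), np.array(y)


def train_logreg_baseline(
    train_data,
    val_data=None,
    C: float = 1.0,
    max_iter: int = 200,
    seed: int = 0,
) -> tuple[LogregBaseline, EvaluationReport | None]:
    """Fit the 15,005-coefficient baseline; evaluate pooled over val data.

    Features are z-scored on the training set (zero-variance bins become
    constant zeros and cannot contribute).  Each epoch is classified
    independently — the baseline has no temporal context by design.
    """
    X, y = _epoch_features_labels(train_data)
    if len(np.unique(y)) < 2:
        raise ValueError("training data has fewer than two stage classes")
    scaler = StandardScaler().fit(X)
    clf = LogisticRegression(
        C=C, max_iter=max_iter, random_state=seed, solver="lbfgs"
    )
    clf.fit(scaler.transform(X), y)
    baseline = LogregBaseline(scaler=scaler, clf=clf)
    report = None
    if val_data:
        preds, truths = [], []
        for rec, hyp in val_data:
            pred = baseline.predict_recording(rec)
            n = min(len(pred), len(hyp))
            preds.extend(pred.stages[:n])
            truths.extend(hyp.stages[:n])
        report = evaluate(Hypnogram(stages=preds), Hypnogram(stages=truths))
    return baseline, report
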