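"""Signal chain from raw 1000 Hz EEG to model-ready 100 Hz windows.

The chain mirrors a wearable front-end: a single-pole 0.3 Hz high-pass to
remove electrode drift, a 60 Hz mains notch, an 8th-order 40 Hz Chebyshev
type-I anti-alias low-pass, and x10 decimation to 100 Hz.  All filters run
causally (forward only) by default, matching real-time streaming use; a
zero-phase mode is available for offline work.

Also provides the mastoid-referenced frontal-channel approximation
FPz-M2 ~ ((FP1-M2) + (FP2-M2)) / 2 used when no FPz electrode exists.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .core import EegRecording, MODEL_RATE, WINDOW_SAMPLES

RAW_RATE = 1000
DECIMATION = 10

# Filter design constants; overridable via the function arguments.
HIGHPASS_HZ = 0.3
NOTCH_HZ = 60.0
NOTCH_Q = 30.0
ANTIALIAS_HZ = 40.0
ANTIALIAS_ORDER = 8
ANTIALIAS_RIPPLE_DB = 0.5


def approximate_fpz_m2(
    fp1: np.ndarray, fp2: np.ndarray, m2: np.ndarray
) -> np.ndarray:
    """Average of FP1 and FP2 after re-referencing both to M2."""
    fp1 = np.asarray(fp1, dtype=np.float64)
    fp2 = np.asarray(fp2, dtype=np.float64)
    m2 = np.asarray(m2, dtype=np.float64)
    if not (fp1.shape == fp2.shape == m2.shape):
        raise ValueError("FP1, FP2 and M2 must have identical lengths")
    return ((fp1 - m2) + (fp2 - m2)) / 2.0


def _design_chain(rate: float, highpass_hz, notch_hz, notch_q, aa_hz, aa_order, aa_ripple):
    """Second-order-section cascades for the three filters at ``rate``."""
    hp = signal.butter(1, highpass_hz, btype="highpass", fs=rate, output="sos")
    b, a = signal.iirnotch(notch_hz, notch_q, fs=rate)
    notch = signal.tf2sos(b, a)
    aa = signal.cheby1(aa_order, aa_ripple, aa_hz, btype="lowpass", fs=rate, output="sos")
    return hp, notch, aa


def preprocess_raw(
    recording: EegRecording,
    zero_phase: bool = False,
    highpass_hz: float = HIGHPASS_HZ,
    notch_hz: float = NOTCH_HZ,
    notch_q: float = NOTCH_Q,
    antialias_hz: float = ANTIALIAS_HZ,
    antialias_order: int = ANTIALIAS_ORDER,
    antialias_ripple_db: float = ANTIALIAS_RIPPLE_DB,
) -> EegRecording:
    """Run the full chain on a 1000 Hz recording, returning 100 Hz.

    Already-100 Hz recordings pass through untouched (for data that was
    acquired or simulated directly at the model rate); any other rate is
    rejected.
    """
    if recording.rate == MODEL_RATE:
        return recording
    if recording.rate != RAW_RATE:
        raise ValueError(
            f"expected {RAW_RATE} Hz raw input (or {MODEL_RATE} Hz pass-through), "
            f"got {recording.rate} Hz"
        )
    hp, notch, aa = _design_chain(
        recording.rate, highpass_hz, notch_hz, notch_q,
        antialias_hz, antialias_order, antialias_ripple_db,
    )
    filt = signal.sosfiltfilt if zero_phase else signal.sosfilt
    x = recording.samples
    x = filt(hp, x)
    x = filt(notch, x)
    x = filt(aa, x)
    x = x[::DECIMATION]
    return EegRecording(
        samples=np.asarray(x, dtype=np.float64),
        rate=MODEL_RATE,
        subject_id=recording.subject_id,
        age=recording.age,
        gender=recording.gender,
        channel_label=recording.channel_label,
    )


def segment_into_windows(recording: EegRecording) -> np.ndarray:
    """Cut a 100 Hz recording into consecutive 3000-sample windows.

    Window k spans samples [3000k, 3000k+3000); a trailing partial window
    is dropped.  Returns an array of shape (n_windows, 3000).
    """
    if recording.rate != MODEL_RATE:
        raise ValueError(f"windowing requires {MODEL_RATE} Hz input")
    n = len(recording.samples) // WINDOW_SAMPLES
    return recording.samples[: n * WINDOW_SAMPLES].reshape(n, WINDOW_SAMPLES)
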