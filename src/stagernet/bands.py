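"""EEG frequency-band conventions and band-power features."""

from __future__ import annotations

import numpy as np
from scipy import signal

#: Classic sleep-EEG bands (Hz).  sigma is the spindle band.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "sigma": (12.0, 14.0),
    "beta": (15.0, 30.0),
    "gamma": (30.0, 50.0),
}

#: Contiguous partition used when labelling a probe peak with one band.
#: beta is widened to [12, 30) so no probe frequency falls between bands.
PARTITION: tuple[tuple[str, float, float], ...] = (
    ("delta", 0.5, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 12.0),
    ("beta", 12.0, 30.0),
    ("gamma", 30.0, 50.0),
)


def band_power(x: np.ndarray, rate: float, lo: float, hi: float) -> float:
    """Mean periodogram power of ``x`` in the band [lo, hi) Hz."""
    freqs, pxx = signal.periodogram(np.asarray(x, dtype=np.float64), fs=rate)
    mask = (freqs >= lo) & (freqs < hi)
    if not mask.any():
        return 0.0
    return float(np.mean(pxx[mask]))


def log_band_powers(
    windows: np.ndarray,
    rate: float,
    bands: tuple[str, ...] = ("delta", "theta", "alpha", "sigma", "beta"),
) -> np.ndarray:
    """Per-window log10 band powers; shape (n_windows, n_bands)."""
    windows = np.atleast_2d(np.asarray(windows, dtype=np.float64))
    freqs, pxx = signal.periodogram(windows, fs=rate, axis=-1)
    out = np.empty((windows.shape[0], len(bands)))
    for j, name in enumerate(bands):
        lo, hi = BANDS[name]
        mask = (freqs >= lo) & (freqs < hi)
        out[:, j] = np.log10(np.mean(pxx[:, mask], axis=-1) + 1e-30)
    return out
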