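"""Synthetic sleep-EEG benchmark generator.

Produces overnight hypnograms and matching single-channel EEG with the
statistical structure a sleep stager exploits:

* hypnograms come from a cycle-modulated Markov chain over the six stage
  codes, tuned so long runs of N2/N3, short N1 transitions, a ~90-minute
  NREM/REM alternation and realistic whole-night stage proportions
  (roughly 16% wake, 13.5% REM, 2.5% N1, 38.9% N2, 18% N3, 11.1% unknown)
  emerge from two knobs (per-stage persistence and target proportions);
* EEG is built per epoch as a sum of narrow-band oscillations chosen for
  the epoch's stage (alpha-dominant wake, low-amplitude theta N1, theta
  plus 13 Hz spindle bursts in N2, high-amplitude delta in N3, mixed
  theta/beta REM) plus broadband noise, cross-faded over 1 s at epoch
  boundaries; UNKNOWN epochs get high-amplitude broadband artifact bursts;
* cohorts carry realistic inter-subject covariate shift — per-subject
  amplitude gains (scalp EEG amplitudes vary 2-3x between people),
  per-subject shifts of the oscillation peak frequencies (individual
  alpha/spindle peaks spread over ~2 Hz) and slow within-night amplitude
  drift — so classifiers without temporal context or cross-subject
  robustness degrade on held-out subjects, as they do on real EEG.

Everything is deterministic under a fixed seed.  The generator emulates
spectral stage signatures and macro-structure only — it contains no
physiological noise sources, arousals, or age-dependent spectral change,
so results on it bound algorithmic correctness, not clinical performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import EegRecording, EPOCH_SECONDS, Hypnogram, MODEL_RATE, SleepStage

_SCORED = [SleepStage.N3, SleepStage.N2, SleepStage.N1, SleepStage.REM, SleepStage.WAKE]

#: Whole-night stage proportions the default model targets.
DEFAULT_PROPORTIONS: dict[SleepStage, float] = {
    SleepStage.WAKE: 0.160,
    SleepStage.REM: 0.135,
    SleepStage.N1: 0.025,
    SleepStage.N2: 0.389,
    SleepStage.N3: 0.180,
    SleepStage.UNKNOWN: 0.111,
}

#: Per-stage self-transition probability per 30-s epoch.  1/(1-p) is the
#: mean dwell: ~6 min for N3, ~7 min for N2, ~8 min for REM, ~5 min for
#: WAKE, ~1.5 min for transitional N1.
_PERSISTENCE: dict[SleepStage, float] = {
    SleepStage.N3: 0.92,
    SleepStage.N2: 0.93,
    SleepStage.N1: 0.65,
    SleepStage.REM: 0.94,
    SleepStage.WAKE: 0.90,
}

#: Off-diagonal jump distribution of the default chain, calibrated by
#: fixed-point iteration so the gated, cycle-modulated chain's empirical
#: stage occupancy matches DEFAULT_PROPORTIONS (the plain closed-form
#: q_j ~ pi_j*(1-s_j) is biased once the REM/N3 cycle gates are active).
_DEFAULT_JUMP: dict[SleepStage, float] = {
    SleepStage.N3: 0.19864,
    SleepStage.N2: 0.37102,
    SleepStage.N1: 0.11108,
    SleepStage.REM: 0.11174,
    SleepStage.WAKE: 0.20753,
}


@dataclass
class Component:
    """One oscillatory constituent of a stage's EEG."""

    center_hz: float
    bandwidth_hz: float
    rms_uv: float
    burst: bool = False  # duty-cycled 0.5-1 s bursts (sleep spindles)


@dataclass
class StageSpectralProfile:
    """Oscillatory components plus broadband noise RMS for each stage."""

    components: dict[SleepStage, list[Component]]
    noise_rms: dict[SleepStage, float]
    #: artifact amplitude multiplier for UNKNOWN epochs
    artifact_gain: float = 5.0

    def __post_init__(self) -> None:
        for comps in self.components.values():
            for c in comps:
                if c.rms_uv < 0 or not (0.0 < c.center_hz < 50.0):
                    raise ValueError("component amplitudes >= 0, frequencies in (0,50)")

    def scaled(self, factor: float, freq_shift: float = 0.0) -> "StageSpectralProfile":
        """Copy with amplitudes multiplied by ``factor`` and oscillation
        centers shifted by ``freq_shift`` Hz (subject-level variation;
        slow delta components shift proportionally less so they stay in
        band)."""
        def shift(c: Component) -> float:
            d = freq_shift * min(1.0, c.center_hz / 6.0)
            return float(np.clip(c.center_hz + d, 0.3, 49.0))

        comps = {
            s: [Component(shift(c), c.bandwidth_hz, c.rms_uv * factor, c.burst)
                for c in lst]
            for s, lst in self.components.items()
        }
        noise = {s: v * factor for s, v in self.noise_rms.items()}
        return StageSpectralProfile(comps, noise, self.artifact_gain)


def default_profile() -> StageSpectralProfile:
    """Stage signatures following standard sleep-EEG phenomenology.

    Amplitudes are chosen so the overall signal sits near the ~50 uV
    peak-to-peak scale typical of sleep EEG.
    """
    comps = {
        SleepStage.WAKE: [Component(10.0, 1.0, 8.0), Component(20.0, 4.0, 4.0)],
        SleepStage.N1: [Component(6.0, 1.0, 7.0)],
        SleepStage.N2: [Component(6.0, 1.0, 5.0), Component(13.0, 0.8, 8.0, burst=True)],
        SleepStage.N3: [Component(1.0, 0.8, 22.0)],
        SleepStage.REM: [Component(5.5, 1.0, 3.0), Component(22.0, 4.0, 5.0)],
        SleepStage.UNKNOWN: [],
    }
    noise = {
        SleepStage.WAKE: 6.0,
        SleepStage.N1: 4.0,
        SleepStage.N2: 6.0,
        SleepStage.N3: 7.0,
        SleepStage.REM: 5.0,
        SleepStage.UNKNOWN: 7.0,
    }
    return StageSpectralProfile(comps, noise)


@dataclass
class HypnogramModel:
    """Cycle-phase-modulated Markov chain over the six stage codes.

    ``transition`` rows/columns follow the integer stage encoding
    (N3, N2, N1, REM, WAKE, UNKNOWN).  During simulation the REM column is
    boosted (by ``gate_gain``) inside a window covering the last
    ``rem_window`` fraction of each ``cycle_period`` and suppressed to 0
    outside it; the N3 column is likewise boosted inside an early window
    of width ``n3_window`` (starting at phase 0.03) and 0 outside.  This
    phase gating — applied to the whole row, so ongoing runs truncate at
    window edges — produces the ~90-min NREM/REM alternation from two
    parameters and keeps per-night stage proportions concentrated around
    their targets.  UNKNOWN labels are overlaid afterwards in contiguous
    runs.
    """

    transition: np.ndarray
    proportions: dict[SleepStage, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    cycle_period: float = 90.0  # minutes
    unknown_fraction: float = DEFAULT_PROPORTIONS[SleepStage.UNKNOWN]
    cycle_modulation: bool = True
    rem_window: float = 0.210  # fraction of the cycle, at its end
    n3_window: float = 0.236  # fraction of the cycle, after phase 0.03
    gate_gain: float = 12.0

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=np.float64)
        if self.transition.shape != (6, 6):
            raise ValueError("transition matrix must be 6x6")
        if np.any(self.transition < 0) or np.any(
            np.abs(self.transition.sum(axis=1) - 1.0) > 1e-9
        ):
            raise ValueError("transition rows must be probability distributions")
        if self.cycle_period <= 0:
            raise ValueError("cycle_period must be positive")


def default_hypnogram_model() -> HypnogramModel:
    """Chain calibrated so empirical occupancy matches the default targets.

    Rows have the form p(i->j) = s_i*delta_ij + (1-s_i)*q_j with the
    pre-calibrated jump distribution q (see ``_DEFAULT_JUMP``); together
    with the REM/N3 cycle gates this yields whole-night stage proportions
    within a few percentage points of ``DEFAULT_PROPORTIONS``.
    """
    q = np.array([_DEFAULT_JUMP[s] for s in _SCORED])
    q /= q.sum()
    T = np.zeros((6, 6))
    for s in _SCORED:
        i = int(s)
        si = _PERSISTENCE[s]
        for t in _SCORED:
            T[i, int(t)] = (1.0 - si) * q[_SCORED.index(t)]
        T[i, i] += si
    # UNKNOWN row: jump straight back into the scored chain
    for t in _SCORED:
        T[int(SleepStage.UNKNOWN), int(t)] = q[_SCORED.index(t)]
    return HypnogramModel(transition=T)


def _modulated_row(row: np.ndarray, phase: float, model: HypnogramModel) -> np.ndarray:
    """Cycle-phase gating of the REM and N3 columns.

    Inside its permitted window a gated stage's column is boosted by
    ``gate_gain`` (fast entry, so the per-cycle block fills the window
    nearly deterministically); outside it the column is zeroed, which also
    truncates an ongoing run at the window edge.  The whole row is then
    renormalized; degenerate rows (e.g. absorbing states whose mass would
    vanish) are left unmodulated.
    """
    w = np.ones(6)
    w[int(SleepStage.REM)] = model.gate_gain if phase >= 1.0 - model.rem_window else 0.0
    in_n3 = 0.03 <= phase < 0.03 + model.n3_window
    w[int(SleepStage.N3)] = model.gate_gain if in_n3 else 0.0
    out = row * w
    total = out.sum()
    if total <= 0.0:
        return row
    return out / total


def simulate_hypnogram(
    model: HypnogramModel, n_epochs: int, rng_seed: int | np.random.Generator
) -> Hypnogram:
    """Draw a hypnogram of ``n_epochs`` 30-s epochs from the model."""
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    rng = np.random.default_rng(rng_seed)
    epochs_per_cycle = model.cycle_period * 60.0 / EPOCH_SECONDS
    # start in WAKE (sleep onset) unless WAKE cannot occur at all
    state = int(SleepStage.WAKE)
    codes = np.empty(n_epochs, dtype=np.int64)
    codes[0] = state
    for t in range(1, n_epochs):
        row = model.transition[state]
        if model.cycle_modulation:
            phase = (t % epochs_per_cycle) / epochs_per_cycle
            row = _modulated_row(row, phase, model)
        state = int(rng.choice(6, p=row))
        codes[t] = state
    _overlay_unknown(codes, model.unknown_fraction, rng)
    return Hypnogram(stages=[SleepStage(c) for c in codes])


def _overlay_unknown(codes: np.ndarray, fraction: float, rng) -> None:
    """Relabel ~fraction of epochs UNKNOWN in contiguous runs (in place)."""
    n = len(codes)
    target = int(round(fraction * n))
    marked = np.zeros(n, dtype=bool)
    need = target
    attempts = 0
    while need > 0 and attempts < 20 * n + 20:
        attempts += 1
        start = int(rng.integers(0, n))
        length = int(rng.integers(2, 13))  # 1-6 min artifact runs
        sl = slice(start, min(start + length, n))
        fresh = np.flatnonzero(~marked[sl])
        take = fresh[:need]
        marked[np.arange(sl.start, sl.stop)[take]] = True
        need = target - int(marked.sum())
    codes[marked] = int(SleepStage.UNKNOWN)


def synthesize_eeg(
    hypnogram: Hypnogram,
    profile: StageSpectralProfile | None = None,
    rate: int = MODEL_RATE,
    rng_seed: int | np.random.Generator = 0,
    epoch_gain_sd: float = 0.25,
) -> EegRecording:
    """Render a hypnogram into a microvolt EEG trace at ``rate`` Hz.

    Each epoch is synthesized over a support extended by 0.5 s on both
    sides and blended with its neighbours by a linear crossfade, so
    amplitude is continuous across stage changes.  A log-normal gain with
    log-sd ``epoch_gain_sd`` is drawn per epoch and applied to the whole
    epoch (oscillations and noise alike), emulating the slow electrode
    impedance and vigilance drifts of real overnight recordings.
    """
    if rate not in (100, 1000):
        raise ValueError("rate must be 100 or 1000 Hz")
    n_epochs = len(hypnogram)
    if n_epochs == 0:
        raise ValueError("hypnogram is empty")
    profile = profile or default_profile()
    rng = np.random.default_rng(rng_seed)
    L = EPOCH_SECONDS * rate
    h = rate // 2  # half the 1-s crossfade
    total = n_epochs * L
    out = np.zeros(total)
    for e, stage in enumerate(hypnogram.stages):
        s0 = max(0, e * L - h)
        s1 = min(total, (e + 1) * L + h)
        t = np.arange(s0, s1) / rate
        seg = _epoch_signal(stage, profile, t, rate, rng)
        if epoch_gain_sd > 0:
            seg = seg * float(np.exp(rng.normal(0.0, epoch_gain_sd)))
        env = np.ones(s1 - s0)
        if s0 > 0:  # fade in over the leading 1-s overlap
            k = min(2 * h, s1 - s0)
            env[:k] = np.linspace(0.0, 1.0, k, endpoint=False)
        if s1 < total:  # fade out over the trailing 1-s overlap
            k = min(2 * h, s1 - s0)
            env[-k:] = np.minimum(env[-k:], np.linspace(1.0, 0.0, k, endpoint=False))
        out[s0:s1] += seg * env
    return EegRecording(samples=out, rate=float(rate))


def _epoch_signal(stage, profile, t, rate, rng):
    n = len(t)
    sig = np.zeros(n)
    for comp in profile.components.get(stage, []):
        f = comp.center_hz + rng.uniform(-0.5, 0.5) * comp.bandwidth_hz
        phi = rng.uniform(0.0, 2.0 * np.pi)
        carrier = np.sin(2.0 * np.pi * f * t + phi)
        if comp.burst:
            env = _burst_envelope(n, rate, rng)
        else:  # slow amplitude modulation for a natural, non-stationary look
            fm = rng.uniform(0.05, 0.3)
            env = 1.0 + 0.3 * np.sin(2.0 * np.pi * fm * t + rng.uniform(0, 2 * np.pi))
        wave = carrier * env
        r = np.sqrt(np.mean(wave**2))
        if r > 0 and comp.rms_uv > 0:
            sig += wave * (comp.rms_uv / r)
    noise_rms = profile.noise_rms.get(stage, 0.0)
    if stage is SleepStage.UNKNOWN:
        noise_rms = noise_rms * profile.artifact_gain
        if noise_rms > 0:
            sig += rng.normal(0.0, noise_rms, n) * (0.5 + _burst_envelope(n, rate, rng))
            return sig
    if noise_rms > 0:
        sig += rng.normal(0.0, noise_rms, n)
    return sig


def _burst_envelope(n: int, rate: int, rng) -> np.ndarray:
    """0/1 duty-cycle with 0.5-1 s bursts and 1-3 s gaps, smoothed edges."""
    env = np.zeros(n)
    pos = int(rng.uniform(0.0, 2.0) * rate)
    while pos < n:
        dur = int(rng.uniform(0.5, 1.0) * rate)
        env[pos : pos + dur] = 1.0
        pos += dur + int(rng.uniform(1.0, 3.0) * rate)
    k = max(1, rate // 8)
    kernel = np.hanning(2 * k + 1)
    kernel /= kernel.sum()
    return np.convolve(env, kernel, mode="same")


def generate_cohort(
    n_subjects: int,
    nights_per_subject: int = 1,
    hours_per_night: float = 8.0,
    rng_seed: int = 0,
    rate: int = MODEL_RATE,
    model: HypnogramModel | None = None,
    profile: StageSpectralProfile | None = None,
    age_mean: float = 37.0,
    age_sd: float = 6.8,
    amplitude_jitter_sd: float = 0.4,
    freq_shift_sd: float = 1.25,
    epoch_gain_sd: float = 0.25,
) -> list[tuple[EegRecording, Hypnogram]]:
    """Simulate a cohort of overnight recordings with per-subject variation.

    Subjects get distinct ids, ages drawn from N(age_mean, age_sd), balanced
    +1/-1 gender codes, a log-normal per-subject gain on all spectral
    amplitudes, and a Gaussian per-subject shift of the oscillation center
    frequencies (sd ``freq_shift_sd`` Hz, mirroring the ~1 Hz spread of
    individual alpha/spindle peaks), so recordings differ between subjects
    in both amplitude and exact spectral-peak position.  ``epoch_gain_sd``
    additionally varies amplitude epoch-to-epoch within each night.
    """
    if n_subjects < 1 or nights_per_subject < 1 or hours_per_night <= 0:
        raise ValueError("all cohort counts must be >= 1")
    rng = np.random.default_rng(rng_seed)
    model = model or default_hypnogram_model()
    base_profile = profile or default_profile()
    n_epochs = int(round(hours_per_night * 3600 / EPOCH_SECONDS))
    out: list[tuple[EegRecording, Hypnogram]] = []
    for i in range(n_subjects):
        sid = f"s{i + 1:03d}"
        age = float(rng.normal(age_mean, age_sd))
        gender = 1 if i % 2 == 0 else -1
        gain = float(np.exp(rng.normal(0.0, amplitude_jitter_sd)))
        shift = float(rng.normal(0.0, freq_shift_sd))
        subj_profile = base_profile.scaled(gain, freq_shift=shift)
        for _ in range(nights_per_subject):
            hyp = simulate_hypnogram(model, n_epochs, rng)
            rec = synthesize_eeg(
                hyp, subj_profile, rate=rate, rng_seed=rng,
                epoch_gain_sd=epoch_gain_sd,
            )
            rec.subject_id = sid
            rec.age = age
            rec.gender = gender
            out.append((rec, hyp))
    return out
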