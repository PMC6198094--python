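# Methods

## Model

The stager maps a sequence of 30-s, 100 Hz single-channel EEG windows
(3000 samples each) to per-window probabilities over the five scored
stages, in the fixed class order **(N3, N2, N1, REM, WAKE)**.

**Convolutional front end (per window).** Three valid-mode, stride-1 1-D
convolutions with kernel width 8 and 8/16/32 filters, each followed by
ReLU and non-overlapping max-pooling of width 8 (floor mode: the
remainder after the last full pool window is dropped). Output shapes on
3000 samples: (374, 8) → (45, 16) → (4, 32). The final (4, 32) map is
flattened row-major into 128 features. Inputs are scaled by 0.05
(≈ 1/20 µV) so typical EEG lands in a unit-scale range.

**Optional demographics.** Age (divided by 100) and gender (±1) can be
appended to the 128 features (130-wide recurrent input). During training
these can be perturbed — Gaussian age noise and random gender masking to
0 — to model unreliable self-reported metadata.

**Recurrent back end (across windows).** Two unidirectional LSTM layers
of 64 units (gate order i, f, g, o; forget-gate bias initialized to 1),
then a recurrent softmax output layer (LSTM-style gating into 5 output
units). Parameter counts for the baseline: conv 72 + 1,040 + 4,128;
LSTM 49,920 + 33,024; output 1,400; total 89,584. A GRU variant uses 3
gates (z, r, n; reset applied before the candidate matmul), giving 3/4
of the LSTM count per layer. The architecture is fully configurable
(depth, filters, units, activation) with analytic shape/count functions
validated against the realized weight arrays.

**Causality and streaming.** All computation for window *t* uses only
windows ≤ *t*. `StagerModel.step` advances one window with explicit
recurrent state and reproduces whole-sequence inference; `stage_recording`
emits one hard decision per epoch via argmax (ties broken toward the
first class in the fixed order, i.e. deeper sleep).

## Training

- Adam (lr 10⁻³, β₁ 0.9, β₂ 0.999, optional 1/(1+decay·t) schedule),
  full backpropagation through time, float64 throughout.
- Masked softmax cross-entropy: epochs labelled UNKNOWN contribute zero
  loss and zero gradient; the loss is averaged over scored positions.
- Optional L1/L2 penalties on conv and recurrent kernels (never biases)
  and variational dropout (one mask per sequence, shared across time) on
  recurrent inputs and state.
- Glorot-uniform initialization; all randomness derives from a single
  seed via `numpy` `SeedSequence` fan-out, so runs are reproducible.

**Time-shift augmentation.** Training sequences start at a uniformly
random sample offset rather than on epoch boundaries. Each shifted
window takes the label of the annotated epoch containing its center
sample; a center exactly on an epoch boundary belongs to the later
epoch. Windows whose center falls in an UNKNOWN or unannotated epoch are
masked. At evaluation time windows are epoch-aligned (shift 0).

**Cross-validation.** Subjects are shuffled into three groups of
near-equal size; each fold trains on two groups and validates on the
third, so no subject ever appears on both sides (checked by an explicit
isolation audit). Validation Kappa is pooled over the fold's recordings.

## Preprocessing (raw 1000 Hz → model rate)

Causal (single-pass `sosfilt`) by default, in this order:

1. order-1 Butterworth high-pass at 0.3 Hz (drift/DC removal),
2. IIR notch at 60 Hz, quality factor 30 (mains),
3. order-8 Chebyshev-I low-pass at 40 Hz, 0.5 dB ripple (anti-alias),
4. decimation by 10 to 100 Hz (every 10th sample).

A zero-phase variant (`filtfilt`) exists for offline use. 100 Hz input
is passed through unchanged; other rates are rejected rather than
silently resampled. The frontal channel can be approximated as
(Fp1 + Fp2)/2 − M2 when Fpz is absent.

## Evaluation

Cohen's Kappa on the 5×5 count matrix; epochs whose *reference* stage is
UNKNOWN are excluded (the classifier never emits UNKNOWN). Degenerate
marginals (both raters constant on one shared class) score 1 for perfect
agreement, else 0. Aggregation is pooled (union of epochs) or
mean-per-recording. Confusion matrices are row-normalized over true
stages with zero-support rows flagged; precision/recall/F1 are reported
per stage with 0 where undefined.

## Probing and the spectral baseline

**Frequency probing.** Each flattened conv feature's response is its
mean absolute activation to pure sinusoids (0.5–50 Hz in 0.5 Hz steps,
50 µV peak-to-peak), averaged over 8 input phases — a (128, 100) map for
the baseline geometry. A feature's dominant band is the band
(delta 0.5–4, theta 4–8, alpha 8–12, beta 12–30, gamma 30–50 Hz)
containing its peak; its selectivity ratio is in-band mean over overall
mean response. All-zero features are labelled "flat".

**FFT logistic baseline.** Per-epoch multinomial logistic regression on
a complete spectral description of each window: signed real DC and
Nyquist amplitudes, then 1,499 magnitudes and 1,499 phases of the
remaining rfft bins — 3000 values that reconstruct the window exactly
(phase of zero-magnitude bins set to 0). Features are z-scored on the
training set; the fitted model has 5 × 3000 + 5 = 15,005 coefficients.
Each epoch is classified independently — no temporal context — making it
the natural ablation for the recurrent stager.

## Synthetic generator

The generator provides structured, label-consistent data — it is a
benchmarking surrogate, not a biophysical simulation.

**Hypnograms.** A first-order Markov chain over the five stages with
stage-persistence diagonals and empirically plausible stationary
proportions, modulated by a 90-minute cycle: N3 is gated into the early
phase of each cycle and REM into the late phase, reproducing the
classic alternation. A fixed fraction of epochs is overlaid as UNKNOWN
in short runs (2–12 epochs), hitting the target count exactly.

**Signals.** Each stage has a spectral profile: narrow-band oscillatory
components (e.g. ~1 Hz high-amplitude delta in N3; 13 Hz spindle bursts
with on/off envelopes in N2; 10 Hz alpha plus beta in wake) over 1/f-ish
broadband noise, with stage-dependent noise levels and high-RMS artifact
bursts in UNKNOWN epochs.

**Inter-subject variability.** Per subject: a log-normal amplitude gain
(sd 0.4 in log units) and a Gaussian shift of oscillation peak
frequencies (sd 1.25 Hz, scaled down for slow components and clipped to
0.3–49 Hz). Per epoch: a log-normal gain (sd 0.25). Together these
create genuine cross-subject covariate shift: within any one recording
the five stages remain cleanly separable from per-epoch log band powers
(a per-recording nearest-centroid rule recovers ≥ 90% of scored epochs),
but decision boundaries fitted on one set of subjects transfer
imperfectly to unseen subjects — which is what makes held-out-subject
evaluation meaningful and gives temporal-context models a real
advantage over per-epoch spectral classifiers.

**Demographics.** Ages ~ Normal(37, 6.8); genders balanced ±1; subject
IDs `s001`, `s002`, …

## Numerical choices

- float64 everywhere; no stochastic kernels at inference.
- Valid-mode convolution and floor-mode pooling make layer geometry
  exactly analyzable; infeasible geometries raise a configuration error
  instead of silently truncating.
- EDF storage quantizes to 16 bits over the recording's actual range
  and stores the quantum, so write→read round-trips are lossless up to
  documented quantization.
- Checkpoints are deterministic (double-save is byte-identical) and
  refuse to load into a mismatched configuration.

## Limitations

- The synthetic generator's realism is limited: stationary-within-epoch
  narrow-band components, first-order stage dynamics, no age- or
  pathology-dependent spectra, no channel artifacts beyond the UNKNOWN
  bursts. Absolute Kappa values on synthetic cohorts do not predict
  performance on real polysomnography.
- Training is plain numpy on CPU; it is intended for small cohorts and
  reduced models (the desk-scale study trains in minutes, a full-scale
  replication would be slow).
- The per-epoch logistic baseline is fitted with lbfgs to default
  tolerance; its Kappa depends mildly on regularization strength C.
- The stager-vs-baseline ordering on desk-scale cohorts depends on the
  cohort draw: with only three held-out subjects, some seeds produce
  validation subjects close to the training distribution, and the
  per-epoch baseline can win (observed at one sanity seed: baseline
  0.906 vs stager 0.798, while both exceeded 0.6). Larger cohorts and
  full-length training reduce this variance.
- Only one EEG channel and two optional scalar covariates are modelled;
  no EOG/EMG fusion.
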