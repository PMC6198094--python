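# stagernet

Causal CONV/LSTM sleep staging from a single frontal EEG channel, with a
synthetic sleep-EEG generator for download-free benchmarking.

Sleep is scored in 30-second epochs as one of five stages — deep sleep
(N3), light sleep (N2, N1), rapid-eye-movement sleep (REM) and wake —
traditionally by hand from overnight polysomnography. `stagernet`
implements an automatic stager designed for wearable, real-time use:

- **Single channel.** One frontal derivation (Fpz–M2, or an approximation
  from Fp1/Fp2 against a reference), not a full montage.
- **Strictly causal.** The model is a stack of 1-D convolutions over each
  30-s window followed by unidirectional LSTM layers across windows; the
  decision for epoch *t* depends only on epochs ≤ *t*. Inference can run
  window-by-window in a stream (`StagerModel.step`) and matches
  whole-night batch inference exactly (to float tolerance).
- **Compact.** The baseline model has 89,584 trainable parameters
  (conv layers: 72 + 1,040 + 4,128; two 64-unit LSTM layers: 49,920 +
  33,024; recurrent softmax output: 1,400).
- **Chance-corrected evaluation.** Agreement with reference hypnograms is
  measured with Cohen's Kappa (human inter-scorer agreement is ≈ 0.75),
  plus confusion matrices and per-stage precision/recall/F1.

Because real polysomnography cannot be bundled, the package ships a
physiologically structured synthetic generator: a cycle-modulated Markov
hypnogram model plus stage-specific spectral profiles (delta waves in N3,
spindle bursts in N2, alpha in wake, …) with per-subject amplitude and
peak-frequency variability, so that cross-subject generalization — the
actual problem in sleep staging — is non-trivial even on synthetic data.

## Quick start

```python
import numpy as np
from stagernet import (StagerConfig, conv_stack_shapes, count_parameters,
                       generate_cohort, evaluate)
from stagernet.architecture import StagerModel, stage_recording

cfg = StagerConfig()
print("conv shapes:", conv_stack_shapes(cfg))
print("parameters:", count_parameters(cfg))

cohort = generate_cohort(n_subjects=2, hours_per_night=1.0, rng_seed=0)
rec, truth = cohort[0]
print("subject:", rec.subject_id, "age:", round(rec.age, 1),
      "epochs:", len(truth))

model = StagerModel(cfg, seed=0)  # untrained
pred, probs = stage_recording(model, rec)
print("untrained kappa: %.3f" % evaluate(pred, truth).kappa)
```

prints

```
conv shapes: [(374, 8), (45, 16), (4, 32)]
parameters: {'conv': [72, 1040, 4128], 'recurrent': [49920, 33024], 'output': 1400, 'total': 89584}
subject: s001 age: 37.9 epochs: 120
untrained kappa: 0.128
```

## Worked example: held-out-subject training on a synthetic cohort

A reduced desk-scale study — 8 subjects × 4-hour nights, a 16-unit
stager, subject-wise folds — trains in about 8 minutes on one CPU core:

```python
import numpy as np
from stagernet import (StagerConfig, TrainConfig, generate_cohort,
                       train_logreg_baseline, probe_conv_features)
from stagernet.probing import band_selectivity
from stagernet.training import make_cv_folds, train_single

cohort = generate_cohort(8, 1, 4.0, rng_seed=11)
folds = make_cv_folds([rec.subject_id for rec, _ in cohort],
                      np.random.default_rng(11))
train_ids, _ = folds.fold(0)
train_data = [dv for dv in cohort if dv[0].subject_id in train_ids]
val_data = [dv for dv in cohort if dv[0].subject_id not in train_ids]

config = StagerConfig(units_per_layer=16)
tconfig = TrainConfig(seq_len_windows=32, batch_size=16, batches_per_epoch=4,
                      n_epochs=40, eval_every=10, seed=7)
model, curves = train_single(config, tconfig, train_data, val_data, seed=7)
print("val kappa curve:", [round(v, 3) for v in curves.val_kappa
                           if np.isfinite(v)])

_, report = train_logreg_baseline(train_data, val_data)
print("logreg baseline kappa: %.3f" % report.kappa)

labels, ratios = band_selectivity(probe_conv_features(model))
print("band-selective conv features: %.1f%%" % (100 * np.mean(ratios >= 2)))
```

Measured output (fixed seeds, deterministic):

```
val kappa curve: [0.273, 0.625, 0.613, 0.737]
logreg baseline kappa: 0.575
band-selective conv features: 34.4%
```

The causal CONV/LSTM reaches a held-out-subject pooled Kappa of **0.737**,
beating a 15,005-coefficient logistic regression over the complete
per-epoch FFT spectrum (**0.575**) — temporal context and learned features
matter precisely because subjects differ in amplitude and peak frequency.
Probing the trained convolutions with pure sinusoids (0.5–50 Hz) shows
34% of the 128 flattened conv features responding selectively
(in-band/overall mean ratio ≥ 2) to classic EEG bands. At this desk
scale the margin over the baseline varies with the cohort draw (see the
limitations in `docs/methods.md`).

## Command line

```bash
stagernet simulate --subjects 8 --hours 4 --seed 11 --out data/
stagernet describe
stagernet train --data data/ --out runs/ --fold 0
stagernet evaluate --pred pred.csv --truth truth.csv --report report.json
stagernet probe --model runs/fold0.ckpt --out map.csv
stagernet baseline-logreg --data data/ --out logreg.json
```

Recordings are EDF (16-bit, with lossless round-trip via stored
quantization), hypnograms are one-stage-per-line CSV/TXT
(`W/N1/N2/N3/R/U`, with legacy `S3/S4` mapped to N3), demographics a YAML
sidecar. Raw 1000 Hz recordings are preprocessed causally (0.3 Hz
high-pass, 60 Hz notch, 40 Hz Chebyshev-I anti-alias, ×10 decimation to
100 Hz).

## Reproduction

To reproduce the headline numbers end to end:

```bash
pip install --no-build-isolation -e .
pytest -q                                   # full suite, ~12 min
python scripts/acceptance.py --seed 0 --out acceptance.json
```

The test suite includes six end-to-end acceptance tests
(`tests/test_acceptance.py`): structural exactness of the architecture,
metric correctness against first-principles oracles, causality/streaming
equivalence, augmentation label semantics, the desk-scale
held-out-subject study above (pooled Kappa ≥ 0.6 and CONV/LSTM >
FFT-logreg), and conv-feature band selectivity (≥ 25% selective
features). `scripts/acceptance.py` re-runs the same study from scratch
under a caller-chosen seed and writes all quantities as JSON.

See `docs/methods.md` for model and generator details.
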