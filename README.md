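# clss — closed-loop EMG sensing and electrical-stimulation modelling

`clss` is a research toolkit for closed-loop myoelectric interaction:
it recognizes hand gestures from multichannel surface EMG and models
the transcutaneous electrical stimulation (ES) that evokes them. It
is aimed at researchers prototyping sensing–stimulation loops and
electrode layouts for the forearm.

The package covers five connected pieces:

1. **Synthetic EMG** — a motor-unit-based generator for a 4-channel
   (dorsal + volar forearm), 9-gesture, multi-subject acquisition:
   gamma-renewal motor-unit spike trains convolved with
   charge-balanced MUAP waveforms, plus broadband noise, baseline
   wander, 50 Hz powerline interference and slow drift.
2. **Preprocessing & features** — 10–500 Hz zero-phase band-pass,
   drift-compensating adaptive normalization (Holt level+trend
   running statistics), 10-s Hamming windows, and 18 features per
   channel per window: ME, EMAV, AAC, MFL, SKEW, KURT, VAR, SD, RMS,
   ZCR, IEMG, ASS, WAMP, LOGD plus spectral energy fractions
   (<20 Hz, 20–50 Hz, >50 Hz) and the median frequency.
3. **Classifier** — a compact ShuffleNetV2-style network (channel
   split, depthwise + pointwise convolutions, channel shuffle, global
   average pooling; ~32k parameters) over the channels × 18 window
   map, trained with Adam on an 80/20 shuffled split; evaluation
   yields the 9×9 confusion matrix and a t-SNE embedding of
   penultimate activations. Implemented in pure NumPy with verified
   manual backpropagation.
4. **Stimulation simulator** — the classical two-step model: a
   finite-volume solve of the quasi-static potential
   ∇·(σ∇V) = 0 in a four-layer cylindrical forearm under surface
   electrode patches (with electrode–skin contact impedance), then a
   McNeal cable model with CRRSS mammalian nodal kinetics for
   myelinated fibers at depths 1–16 mm, driven by the activating
   function (the axial second difference of the extracellular
   potential). Electrode-design sweeps count activated fibers versus
   voltage, spacing, size, shape, orientation and polarity.
5. **Closed loop** — charge-balanced symmetric biphasic waveforms,
   a deterministic gesture → electrode-channel mapping (dorsal for
   extension, volar for flexion), a rest gate, and the aggregated
   angle error √(Σᵢ(θᵢᴱˢ − θᵢˢᵖᵒⁿᵗ)²) over 14 finger/wrist joints.

## Worked example

```python
import numpy as np
from clss.config import SystemConfig
from clss.synthetic import SyntheticSpec, generate_dataset
from clss.closed_loop import extract_feature_dataset
from clss.classifier import ModelConfig, build_model, split_dataset, train, evaluate

cfg = SystemConfig()                                  # 2 kHz, 10-500 Hz, 10-s windows
spec = SyntheticSpec(n_subjects=6, windows_per_class=8)
recs = generate_dataset(spec, cfg, 1)                 # 54 labeled recordings
tr, te = split_dataset(9 * 6 * 8, 0.8, seed=1)        # 80/20 shuffled split
tensor = extract_feature_dataset(recs, cfg, train_indices=tr)
print(tensor.values.shape)

mcfg = ModelConfig(seed=1)                            # 150 epochs by default
model = build_model(mcfg)
history = train(model, tensor.values[tr], tensor.labels[tr], mcfg)
report = evaluate(model, tensor.values[te], tensor.labels[te], history)
print(f"train accuracy {history['accuracy'][-1]:.3f}")
print(f"test accuracy  {report.accuracy:.3f}")
```

Output:

```
(432, 4, 18)
train accuracy 1.000
test accuracy  0.965
```

The tensor is the 3-D dataset (432 windows × 4 channels × 18
features) the network consumes; at the default 12 dB synthetic SNR
the nine gestures are cleanly separable and both accuracies sit
comfortably above the 90% / 96.14% floors the pipeline is expected to
attain.

An electrode-design sweep on a coarse grid:

```python
from clss.volume_conductor import ArmModel
from clss.fiber_activation import build_population, run_sweep

arm = ArmModel(dr_target_mm=2.0, dtheta_deg=7.5, dz_mm=5.0)
pop = build_population(azimuth_step_deg=7.5, arm=arm)
print(run_sweep("voltage", [10, 20, 30, 40, 50, 60], arm=arm, population=pop))
```

```
   voltage  activated_count   config_hash
0       10                3  ee3f4d647a4b
1       20               17  ee3f4d647a4b
2       30               24  ee3f4d647a4b
3       40               26  ee3f4d647a4b
4       50               33  ee3f4d647a4b
5       60               39  ee3f4d647a4b
```

The activated-fiber count rises monotonically with the applied
potential; spacing, diameter, orientation and polarity sweeps work
the same way.

A `clss` console script wraps the main stages
(`clss simulate-emg`, `clss extract-features`, `clss train`,
`clss field-solve`, `clss sweep`, `clss closed-loop`; see
`clss --help`).

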