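# Methods

This note documents the models implemented in `clss`, the choices
behind their parameters, and what the synthetic experiments do and do
not demonstrate.

## Scope

The package reimplements the computational core of a closed-loop
surface-EMG sensing / transcutaneous electrical-stimulation (ES)
system for hand-gesture interaction: synthetic multichannel EMG
generation, the preprocessing and 18-feature window pipeline, a
compact shuffle-block convolutional classifier for nine gestures, a
two-step forearm volume-conductor + nerve-fiber activation simulator
for electrode design, charge-balanced biphasic stimulation planning,
and the closed-loop orchestration that maps recognized gestures to
stimulation programs. Hardware (ink chemistry, flexible circuits,
BLE firmware) and human-subject experiments are out of scope.

## Synthetic EMG generator

No public dataset accompanies the system, so the generator is the
study population. It emulates a 4-bipolar-channel (two dorsal, two
volar forearm pairs), 9-gesture, 13-virtual-subject acquisition at
2000 Hz. Per channel the trace is

```
subject_gain * sum_units( gamma-renewal spike train  (*)  MUAP )
  + white noise + baseline wander + 50 Hz powerline + linear drift
```

* **MUAP shape** — second derivative of a Gaussian (Ricker wavelet),
  optionally skewed, Hann-tapered and mean-subtracted so every
  waveform has exactly zero net area; amplitude 100 µV, duration
  15 ms. Band-limited within the 10–500 Hz analysis band.
* **Firing statistics** — 8 motor units per channel, gamma-renewal
  trains with shape 4 (physiological regularity; shape 1 would be
  Poisson). Mean rate ramps from 8 Hz (recruitment floor) to 30 Hz at
  full drive.
* **Gesture code** — a fixed, documented 9×4 activation matrix maps
  each gesture to per-channel drives in [0, 1]; extension gestures
  (WE, HO) load the dorsal channels, flexion gestures (WF, PG, TF)
  the volar ones. Drive modulates firing rate, MUAP amplitude and
  MUAP width (stronger drive → sharper waveforms), so classes differ
  in burst density and spectral content, not only in amplitude.
* **Noise convention** — the white-noise floor is *absolute*: its RMS
  is set from `snr_db` (default 12 dB) relative to the clean signal
  at drive 1.0, calibrated once by a deterministic 20-s reference
  simulation. A per-channel-relative noise floor would equalize all
  channels' SNR, erase class information under adaptive
  normalization, and is physically wrong (amplifier noise does not
  track muscle drive). Powerline amplitude is 10% of the full-drive
  RMS (50 Hz mains); baseline wander is a 0.8 Hz, 200 µV sinusoid
  plus a 2 µV/s linear drift.
* **Subject variability** — one multiplicative lognormal gain per
  virtual subject (σ = 0.2).

What the generator does **not** emulate: motion artifacts, electrode
lift-off, MUAP superposition nonlinearity, fatigue-induced spectral
compression, inter-session electrode displacement, or realistic
cross-talk. Passing classification tests therefore demonstrate that
the pipeline and model are implemented correctly and can extract the
class structure the generator encodes — not field performance on real
recordings.

## Preprocessing

10–500 Hz 4th-order Butterworth applied forward-backward (zero
phase); 10-s sliding windows with 50% overlap and a Hamming taper;
adaptive normalization with exponentially forgotten running
statistics, applied before the taper.

The running mean uses Holt level + trend smoothing (level half-life
10 s, trend 5 s; variance a plain EWMA). A single EWMA mean lags a
linear ramp by roughly its half-life and therefore never removes
steady drift; the trend term tracks ramps with zero asymptotic error,
which is what "drift compensation" requires. The half-lives are our
choice — shorter tracks drift faster at the cost of flattening slow
genuine amplitude changes; with spectral/burst features carrying the
class information this trade-off is benign.

## Features

Eighteen features per channel per window: fourteen time-domain (mean
energy, enhanced mean absolute value with the central-window exponent
scheme p=0.75 on 0.2N..0.8N else 0.5, average amplitude change,
maximum fractal length, skewness, excess kurtosis, population
variance and SD, RMS, zero crossings, integrated absolute value,
signed-root summation, Willison amplitude with threshold 0.1 in
normalized units, log detector with ε = 1e-12) and four
frequency-domain (energy fractions below 20 Hz, 20–50 Hz, above
50 Hz, and the median frequency) from a Welch PSD with 1-s Hamming
segments at 50% overlap. Every time-domain formula is verified
against a literal per-sample loop oracle to 1e-10 relative. Features
are z-scored per feature using training-partition statistics only.

## Classifier

A ShuffleNetV2-style network over the (channels × 18) window map:
3×3 stem (24 filters) + batch norm + max-pool, then two stages, each
a stride-2 downsampling shuffle block followed by two stride-1 blocks
(channel split, pointwise/depthwise/pointwise branch, concat, channel
shuffle with 2 groups) at widths 48 and 96, global average pooling,
a 64-unit fully connected layer and a 9-way softmax (~32k
parameters). Training: Adam (1e-3), batch 32, cross-entropy,
150 epochs, fully seeded. The layers (convolutions via explicit
kernel-offset accumulation, batch normalization, manual
backpropagation) are implemented in NumPy in `clss.nn`; gradients are
verified against central-difference directional derivatives. The 2-D
embedding of first-fully-connected-layer activations uses t-SNE
(scikit-learn, PCA initialization, seeded).

The reference accuracies (90% held-out, 96.14% final training) are
treated as attainability floors on the synthetic dataset; the
acceptance script reports the 5-seed median on 13 subjects × 9
gestures × 10 windows (1170 windows), a size chosen so five 150-epoch
CPU training runs complete interactively. At 12 dB SNR the synthetic
task is comfortably above both floors (typically ≥ 99%).

## Volume conductor (simulation step one)

Quasi-static potential ∇·(σ∇V) = 0 in concentric cylinders: bone
r ≤ 10 mm (σ = 0.02 S/m), muscle to 35 mm (0.35, optionally
anisotropic 0.4/0.09), fat to 38.5 mm (0.04), skin to 40 mm (0.1),
length 300 mm. These are literature-typical defaults, configurable.

Discretization: cell-centered finite volumes on a cylindrical grid.
Radial cells are sized per layer (target 1 mm, at least two cells per
layer — a uniform 1 mm grid could not resolve the 1.5 mm skin);
azimuth 5°, axial 2.5 mm by default (~350k unknowns, a few seconds
with diagonally preconditioned conjugate gradients; small grids use a
direct solve). Conductivities are harmonically averaged at radial
faces. The scheme is an M-matrix, so the discrete maximum principle
holds (asserted on every test solve).

Electrodes are skin-surface patches (circle, square, equilateral
triangle, rectangle with circumferential or axial orientation) at
fixed potential, coupled through a contact impedance (complete-
electrode-model style Robin coupling, default 2 kΩ·cm², normalized by
the analytic patch area and spread over the rasterized cells).
Without it, delivered current scales with patch perimeter rather than
area (an equal-area triangle passed 21% more current than a circle),
which is unphysical for transcutaneous stimulation where the stratum
corneum dominates the interface. Footprints are rasterized with 4×4
supersampling at half coverage so sharp corners do not leave
grid-scale slivers; sub-cell patches keep their best-covered cells.

Validation: antisymmetry for a ±V pair, linearity in the applied
potentials, superposition of monopole solves, charge conservation
between the electrodes (< 2%), grid-refinement stability (< 5% on
sampled fiber potentials when the default spacing is halved), and the
half-space point-source law V = I/(2πσr) within 10% over 3–10 mm,
checked in potential-difference form against a 25-mm reference depth
because the finite cylinder adds a series channel-resistance offset
that the difference cancels.

## Fiber activation (simulation step two)

Fibers run parallel to the arm axis at depths 1–16 mm (1 mm steps)
and azimuths every 5°; default diameter 10 µm, node-of-Ranvier
spacing 100 × diameter. The node count follows from a fixed 200 mm
axial span so fibers of any diameter cover the same extent and pass
beneath the electrodes (a fixed node count would move the fiber ends
under the electrodes for thick fibers and create artificial
end-node excitation).

Nodal membranes use the CRRSS mammalian kinetics (sodium m²h + leak,
37 °C; g_Na = 1445 mS/cm², g_L = 128 mS/cm², E_Na = 115 mV above the
−80 mV rest, c_m = 2.5 µF/cm², axoplasmic resistivity 54.7 Ω·cm,
node length 1.5 µm, axon/fiber ratio 0.7). Gating rates are clamped
to [−120, 180] mV where they are already saturated, to avoid
overflow during strongly supra-threshold transients. The McNeal
cable equation couples nodes through the axial conductance with the
extracellular potential entering via its second difference (the
activating function); ends are sealed. Integration is semi-implicit
backward Euler at 5 µs (gates by exponential Euler, the linearized
membrane + axial system by a vectorized tridiagonal solve over the
whole fiber population at once) for one stimulus pulse plus 1 ms.
A fiber is activated when any node crosses 0 mV absolute (80 mV
depolarization); the criterion is configurable.

Waveform coupling uses quasi-static separability: the field is
solved once per geometry and rescaled per time step by the stimulus
waveform (so a voltage sweep needs a single solve). Electrode
*polarity* comparisons use a monophasic test pulse: a symmetric
biphasic pulse contains both polarities and would mask the
cathode/anode asymmetry.

Sweeps (`run_sweep`) cover voltage (default 10–60 V), spacing
(35–115 mm), electrode diameter, shape, rectangle orientation and
polarity; the base configuration is a bipolar pair of 30-mm circles
75 mm apart at ±V/2. Tables carry a configuration hash. A fast
activating-function screen (`af_screen`) calibrates the
threshold-equivalent AF peak on a strongly driven reference fiber by
amplitude bisection and agrees with the full cable model away from
the threshold boundary.

## Stimulation planning and closed loop

Symmetric biphasic pulses (default 200 µs phases, no interphase gap,
20 Hz) are charge balanced exactly by construction; pulses are never
truncated mid-phase. The gesture→channel mapping routes extension
gestures to dorsal channels and flexion gestures to volar channels
(the deployed system tunes this per subject; the shipped table is the
documented default). The closed loop band-passes and normalizes the
incoming stream, extracts features with the stored training z-scoring
statistics, classifies each window, and emits the mapped program; a
minimum-RMS gate (default 25 µV on the band-passed signal) suppresses
stimulation on rest windows. The aggregated angle error between
stimulated and spontaneous gestures is the root of the sum of squared
differences across a documented 14-joint list (thumb CMC/MCP/IP,
MCP + PIP of the four fingers, wrist flexion-extension, index and
middle DIP).

## Known limitations

* The generator's realism is by construction, not fit to data; all
  classification results are upper bounds relative to real EMG.
* The volume conductor is an idealized concentric cylinder with
  purely resistive tissue; no capacitive/dispersive properties, no
  MRI-derived anatomy.
* Equal-area electrode shape comparisons: circle and square agree
  (typically within 10%), but the equal-area triangle activates
  ~40–70% more fibers than the circle across all operating points we
  examined, even after the contact impedance equalizes delivered
  current. The excess is intrinsic to this idealization: the
  triangle's wide, axially narrow base behaves like a short
  circumferential strip, whose sharply peaked axial potential profile
  yields a larger activating function on the uniform depth × azimuth
  fiber grid — the same mechanism that makes a circumferential
  rectangle out-activate an axial one. A model with anatomically
  clustered nerve trunks or dispersive tissue may well close the gap;
  this one does not.
* Single fiber diameter per population; no recruitment-order
  distribution, no muscle-force transduction.
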