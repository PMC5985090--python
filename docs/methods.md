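# Methods

## Signal model and scope

The package decodes three right-hand movements — thumb, index finger,
fist — from 14-channel scalp EEG sampled at 128 Hz (Emotiv montage:
AF3, F7, F3, FC5, T7, P7, O1, O2, P8, T8, FC6, F4, F8, AF4). The
working assumption is the standard sensorimotor-rhythm one: movement
modulates the power of Mu (~8–13 Hz) and Beta (~13–30 Hz) oscillations
over motor cortex, most visibly at F3 and FC5, and a per-channel
band-power summary of the 8–30 Hz band carries enough of that
modulation to separate the classes. The hardware side of the original
system (microcontroller, SD/SPI transport, H-bridge motor drive) is out
of scope; the streaming loop is simulated by replaying trials in 250 ms
chunks, and motor commands are emitted as records.

## Filtering

Band limiting is a cascade of two order-2 digital Butterworth sections
(8 Hz high-pass, then 30 Hz low-pass), each applied zero-phase:

* The recursion is the direct difference equation with zero initial
  state. The shipped coefficient constants are the original 4-decimal
  design; `design_butterworth` re-derives them at full precision
  (bilinear transform with prewarping, via `scipy.signal.butter`). The
  4-decimal rounding perturbs the response by well under 0.1 % in the
  passband; both paths are exposed and the constants are the default,
  mirroring the embedded implementation.
* Each pass pads the signal by **odd (antisymmetric) reflection of 9
  samples per end** — 3·(order+1), the de-facto standard for
  forward–backward IIR filtering — then filters forward, reverses,
  filters again, reverses, and truncates. The pad length and scheme are
  arguments, since the original firmware's padding is unspecified; 9 is
  the default everywhere.
* Zero initial conditions distinguish this implementation from
  `scipy.signal.filtfilt` (which seeds the filter state); the padding
  absorbs the start-up transient instead. Tests therefore compare
  against an independently coded pad + `lfilter` forward/backward
  oracle, with agreement to 1e−9.
* A 32-sample chunk is filtered as a unit (padded to 50 samples per
  pass). Edge transients decay like |p|ⁿ with |p| ≈ 0.76, so roughly
  the outer 10 samples of a chunk carry residual transient; this is
  inherent to chunkwise zero-phase filtering at this block size and is
  identical for all classes, so it does not bias classification.

## Features

Per channel and chunk: four contiguous 8-sample (62.5 ms) windows, no
overlap (4 × 62.5 ms exactly tiles 250 ms); symmetric Hamming taper;
8-point DFT; two-sided periodogram `|X(k)|²/(Fs·L·U)` with
`U = (1/L)·Σw²` (≈ 0.3046 for N = 8); bin-wise average over the four
windows; division by 2π; mean over the 8 bins. The 1/(2π) factor is a
pure scale kept for fidelity with the original implementation — it
cancels in any classifier that is scale-equivariant in the features.
All 8 two-sided bins are kept rather than folding to one side; with
8-point segments the bin spacing is 16 Hz, so no within-band bin
selection is possible and band limiting comes entirely from the
preceding filter. The feature vector is the 14 per-channel band powers
in canonical channel order.

## Classifier

A decision cascade of two binary logistic models: network I (fist vs.
not-fist) on all data, network II (thumb vs. index) trained only on the
thumb/index subset and consulted only when network I rules out fist.
The sigmoid score uses a leading-1 augmentation for the intercept
(15 coefficients per network). Decision threshold is 0.5 with the exact
tie assigned to class 2 — a measure-zero event, fixed for determinism.

Training is iteratively reweighted least squares on the ridge-penalized
binomial log-likelihood (intercept unpenalized), to gradient norm
< 1e−8 or 100 iterations; non-convergence is flagged on the model and
warned. The default ridge of 1e−8 is a numerical stabilizer. IRLS was
chosen over a generic optimizer for determinism: no random
initialization, no data-order dependence. Agreement with scikit-learn's
lbfgs logistic regression at matched penalty is verified in the tests
(coefficients to ~1e−3), and simulated 14-dimensional logistic data at
n = 2000 is recovered with coefficient RMSE < 0.15.

The train/test protocol is a stratified 75/25 split of the chunk pool
with a fixed, configurable seed, then 31 randomly chosen test chunks
per class feed the confusion matrix — matching the original embedded
evaluation's test-set size.

## Evaluation and control

Per-class accuracy is recall (diagonal over row sum) in integer
percent; the summary is the **macro** mean of the un-rounded recalls,
then rounded. Rounding is half-away-from-zero throughout. One cell of
the original published table (category-I index finger: 16/31 = 51.6 %)
is printed there as 51 % although the rounding used for every other
cell gives 52 %; this package applies the consistent rule and the
1-point discrepancy is documented here rather than reproduced. With 31
test chunks per class the macro and micro means coincide, so the
macro/micro choice is observationally irrelevant at the reference
sizes. Motor commands are a fixed lookup (thumb → On/Off,
index → Off/On, fist → On/On) emitted as records or a CSV trace.

## Synthetic generator and calibration

Each channel is broadband noise (white by default; optionally
1/f-shaped, variance-renormalized) plus fixed-frequency rhythms at 10
and 22 Hz with uniformly random phase per channel and trial. Class
identity enters only through multiplicative rhythm gains at F3 and FC5:

| class | F3 gain | FC5 gain |
|-------|---------|----------|
| thumb | 2.2     | 1.0      |
| index | 1.0     | 2.2      |
| fist  | 2.6     | 2.6      |

All other channels sit at gain 1. Fist raises *both* channels, slightly
above the single-channel boosts: an intermediate fist level would place
its (F3, FC5) power pattern on the segment between the thumb and index
patterns, which no linear stage-I boundary can separate — the
slightly-higher-both pattern keeps the cascade's geometry solvable
while preserving the qualitative "both channels active" signature and a
clear thumb-vs-fist F3 contrast (Cohen's d ≈ 1.4 on per-trial mean
features at the defaults).

Defaults: 10 s trials, rhythm amplitude 6 µV per component, noise
σ = 16 µV. These are calibration constants, not measured physiology;
they were chosen once so that the clean preset's decoded accuracy falls
in the mid-60s-to-high-70s percent band that consumer-headset finger
decoding typically reaches, and they are recorded in every dataset's
`config.yaml`.

The blink regime ("category I" subjects, a high involuntary blink rate)
adds positive half-sine lobes of 0.2–0.4 s at Poisson times (1.5/s in
the preset), amplitude 450 µV, coherent across the six frontal channels
(AF3, AF4, F3, F4, F7, F8). Blink energy is concentrated well below
8 Hz, so the high-pass attenuates but does not remove it; the residual
contaminates F3 features on affected chunks and lowers accuracy
relative to the matched clean preset without destroying it — the same
ordering the original study observed between its subject categories.

Reproducibility: a trial is a pure function of (master seed, per-trial
counter) via `numpy.random.SeedSequence([seed, counter])`; the counter
runs class-major over the dataset.

**What the generator does not emulate:** volume-conducted spatial
correlation between channels, non-stationary rhythm amplitude
(event-related desynchronization time courses), line noise, electrode
drift, or realistic EEG spectral shape beyond the optional 1/f noise.
Passing end-to-end tests therefore demonstrate that the pipeline's
stages compose correctly and recover known band-power structure — not
that the decoder would reach any particular accuracy on real
recordings.

## Problem sizes used in the checks

The end-to-end recovery check uses 20 trials per class (the clean
preset's default) with 31 test chunks per class; the well-separated
regime (gains ×4, σ = 4 µV) and the 5-seed category-I/II comparison use
8 trials per class, which is ample for those contrasts. The two
original headline network accuracies (74 %/76 %) depended on the
unreleased recordings and are not reproduction targets; the pipeline's
numerical behavior is pinned instead by oracle equivalence (filtering,
periodogram Parseval identity, logistic recovery) and synthetic ground
truth.

## Known limitations

* Chunkwise (32-sample) zero-phase filtering leaves edge transients in
  roughly a third of each chunk; whole-trial filtering before chunking
  would reduce this but would not match the embedded processing order.
* The 16 Hz bin spacing makes the "band power" effectively a
  filter-shaped broadband power, not a resolved spectrum; this is
  faithful to the original design, not a recommendation.
* The two-stage cascade propagates stage-I errors; no probability
  calibration or rejection option is provided.
* Floating-point only: the original fixed-point/Arduino arithmetic is
  not emulated.
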