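# Methods

This note documents the models implemented in `spikenc`, the parameter
choices that matter, the numerical conventions, and what the synthetic-data
tests do and do not establish.

## Retinal front end

Images are reduced to a single channel (Rec. 601 luminance weighting for
RGB input) and resized with bilinear interpolation; both are the most
common defaults and the pipeline is insensitive to the exact choice because
the DoG filters that follow are band-pass.

Each DoG kernel is the difference of two *unit-mass* Gaussians, so its
coefficients sum to zero (a constant image produces no response) and the
ON/OFF pair of each scale are exact negatives.  Two presets are built in:

| preset | kernels | sizes | σ pairs | padding |
|---|---|---|---|---|
| `character_natural` | 6 (ON+OFF × 3 scales) | 3, 7, 13 | (3/9, 6/9), (7/9, 14/9), (13/9, 26/9) | 6 |
| `digit` | 2 (ON+OFF) | 7 | (1, 2) | 3 |

All kernels of a preset are embedded centred in the largest kernel's window
(13×13 for `character_natural`) before convolving with the single stated
padding.  This is the only geometry under which one padding amount yields
aligned, equally sized response maps for all three scales; with pad = 6 and
window 13 the maps are exactly input-sized.  Convolution uses the
correlation convention (no kernel flip); the kernels are symmetric, so the
choice is immaterial, but it fixes the orientation of all tests.

Intensity-to-latency coding: sites with response > 50 are sorted in
descending order (ties broken by row-major site index, making the code a
pure function of its input) and split into T = 30 rank-contiguous bins as
equal as possible, the earliest bins absorbing the remainder.  The 50
threshold applies to every preset.  Spike waves are pooled with 2×2
windows, stride 2, keeping the *earliest* spike per window — max pooling of
cumulative spike trains — and ragged edges are dropped.

## IF convolutional layer

Voltage integrates the weighted presynaptic spikes of the *previous* time
step, so a spike at t = 0 can trigger an output spike at t = 1 at the
earliest; spikes in the last input bin influence only the infinite-threshold
feature readout.  Neurons fire at most once per image, which makes the
event set identical to the set of first threshold crossings of the un-reset
voltage; the simulator exploits this by accumulating each presynaptic spike
as one kernel-patch addition and recording first crossings, and is verified
event-for-event against an independent scalar simulator.

Feature extraction sets v_th = ∞: the readout is exactly the weight kernel
correlated with the total spike-count map, computed with a sliding-window
einsum so it matches a direct nested-loop correlation to 1e−10 (an FFT
convolution would not).

## STDP training

The simplified STDP rule is multiplicative, Δw = a± · w(1−w), with
potentiation whenever the presynaptic site spiked at or before the winner's
spike time.  Presynaptic sites that never spike — including zero-padding
sites outside the canvas — are depressed; potentiating silent synapses
would prevent the weights from ever becoming selective.  The rule keeps
weights in [0, 1] algebraically (0 and 1 are fixed points), and the
convergence measure C = Σ w(1−w)/N ∈ [0, 0.25] reaches 0 only at full
saturation.

Choices the dynamics literature fixes but that are worth stating:

* **Initial rates** a⁺ = 0.004, a⁻ = −0.003; **stopping rule** C < 0.01.
* **Rate schedule**: both rates are doubled (ratio preserved) every 500
  weight updates until a⁺ reaches 0.15 (`rate_boost_every`, `a_plus_cap`;
  set `rate_boost_every=None` for fixed rates).  This is the standard
  accelerated schedule of the unsupervised spiking-CNN literature and is
  what makes full saturation of 64 × 6 × 5 × 5 weights reachable with one
  winner per image inside a 64-epoch budget: at fixed rate 0.004 each
  weight moves by at most 0.001 per update, and a weight needs ≈ 1400
  updates to saturate, far more than the ≈ 400 updates per channel a
  64-epoch budget provides.
* **Winner policy**: one winner per image (configurable), at most one per
  output channel, ties in spike time broken by highest voltage at firing,
  then deterministically by channel and site index.  Same-channel
  suppression within `inhibition_radius` (default 2) is implied by the
  one-per-channel rule whenever `winners_per_image` ≤ channel count.
* **Initialization**: weights ~ N(0.8, 0.05²) clipped to [0, 1], seeded.
  Starting high lets unsaturated channels fire early and claim winners,
  which spreads learning across all 64 channels.
* **Epoch budget**: 64; non-convergence yields a warning, not an error.

Typical behaviour on 400 synthetic bar/glyph stimuli: C rises slightly at
first (depression drags weights from 0.8 toward 0.5, the maximum of
w(1−w)), then falls steadily as channels become selective, crossing 0.01
after ≈ 30 epochs in ≈ 30 s on one CPU.

## Voxel-wise encoding

The regression of a voxel on the feature vector at one location includes an
intercept (configurable off): measured fMRI amplitudes are not zero-mean,
and omitting the intercept would bias the receptive-field search toward
locations whose features happen to match the response mean.  Folds for the
receptive-field search are contiguous blocks of a seeded shuffle, and R² is
computed on the pooled out-of-fold predictions (not averaged per fold);
zero-variance targets are scored 0.  Ordinary least squares uses the
minimum-norm solution; a rank-deficient fold design falls back to a tiny
ridge (1e−8) with a warning — predictions are then still exact on the
training span but individual weights are not identifiable (the tests skip
weight-recovery assertions for ill-conditioned designs).

Receptive-field ties resolve to the smallest (i, j) in row-major order.
Voxel selection for decoding ranks by *training-set* cross-validated R²,
never test-set accuracy, to keep the downstream decoding evaluation
non-circular.

## Decoding

The log likelihood is computed up to its constant as
−(r − r̂) Σ⁻¹ (r − r̂)′ via a symmetric positive-definite solve (Cholesky),
which preserves the ranking and avoids forming Σ⁻¹.  Σ is the sample
covariance of the training residuals shrunk toward its diagonal with
λ = 0.1 by default: with 200 selected voxels and a few hundred trials the
raw sample covariance is ill-conditioned, and the shrunk estimate stays
invertible whenever the residual variances are positive.  With a diagonal
Σ the likelihood ranking coincides with ranking by noise-variance-weighted
Euclidean distance (tested as a closed-form equivalence).  Default voxel
counts are 200 for reconstruction and 500 for identification; the
reconstruction is the pixel mean of the top-15 priors.  Identification
correlates the observed response vector with each candidate's predicted
vector across the selected voxels; a zero-variance prediction scores −∞.

SSIM uses the library default local window with `data_range=255`.

## Noise ceiling

The signal-variance estimator subtracts the full noise variance from the
variance of the per-image mean response, σ̂²_R = var(μ_R) − σ̂²_N, exactly as
the canonical formula states.  Because μ_R averages n_repeats trials, its
noise contribution is really σ²_N / n_repeats; the corrected subtraction is
available behind `correct_repeat_mean=True` (CLI `--corrected`) without
changing the default.  Negative estimates (noise-dominated voxels) are
clipped to 0 with a warning.  The Monte-Carlo ceiling uses zero-mean draws
(Pearson correlation is location-invariant) and returns the degenerate
cases in closed form: exactly 1 when σ²_N = 0 and 0 when σ²_R = 0 (the
constant-series convention).  The Monte-Carlo mean converges to
σ_R/√(σ²_R + σ²_N), which the tests check within three standard errors.

## Synthetic data

The generators produce bars (single oriented high-contrast strokes at four
orientations), blobs (sums of Gaussian bumps) and glyphs (2–4 jittered
strokes, loosely character-like) with pixels in [0, 255]; 56×56 images with
270/90 train/test trials and 35 test repeats mirror the handwritten-
character experimental scale and are the defaults of the `synth` command.
Ground-truth voxels read out one feature-map location with sparse Gaussian
weights plus i.i.d. Gaussian noise — *exactly* the generative assumption of
the encoding model.  Passing the round-trip tests therefore demonstrates
that the estimation machinery (receptive-field search, regression,
likelihood decoding, ceiling estimation) is correct and self-consistent; it
says nothing about whether real visual cortex is linear in these features,
and the synthetic images lack the spatial statistics, occlusions and
luminance distributions of natural scenes.

## Problem sizes and determinism

Tests and the acceptance script run at deliberately reduced scales chosen
to exercise every code path on a single CPU: 400 training stimuli for the
convergence run, 8×8 maps with 50 replicates for recovery, tens of trials
for the decoding identities.  Every stochastic component takes an explicit
seed (numpy `default_rng`), CSV floats are written and parsed in round-trip
mode, and HDF5 datasets disable timestamp tracking, so identical seeded
runs produce byte-identical files.

## Known limitations

* One convolutional layer only; no leaky-IF or conductance-based neurons.
* The regression is linear with a single receptive-field location per
  voxel; no compressive nonlinearity or multi-location pooling.
* Reconstruction is selection-plus-averaging over a prior set; it cannot
  synthesise content absent from the priors, and colour is not modelled.
* The noise model behind both the covariance Σ and the ceiling is
  i.i.d.-across-trials Gaussian; serial correlations in real fMRI are not
  represented.
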