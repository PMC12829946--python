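# Methods

`predscan` implements an analysis of how the spatial predictability of a
neuron's receptive-field (RF) image patch modulates visual-cortical firing,
together with a synthetic-data generator that provides ground truth for
validating every stage of the analysis. This note documents the models,
the defaults and their rationale, the numerical choices, and what the
synthetic studies do and do not establish.

## Spatial predictability by mask-and-inpaint

For each unit, the FWHM ellipse of its fitted 2-D Gaussian RF is removed
from the stimulus image and filled in by an inpainter; unpredictability is
the distance between the actual and the predicted patch, measured in the
feature space of a five-stage convolutional hierarchy. Both patches are
square crops of side 1.5x the RF FWHM diameter centred on the RF. Per
level l, d_l is the plain l2 norm of the difference of the stage-l feature
tensors; the overall estimate is the arithmetic mean of d_1..d_5. Using a
feature-space rather than pixel distance makes the measure insensitive to
pixel-level artifacts while separating low-level (edge) from high-level
(texture/arrangement) prediction failure.

### Inpainters

* **PConvUNet** — a UNet over partial convolutions. A partial convolution
  restricts the kernel to valid pixels and renormalizes by
  `window_size / valid_count`; the mask is updated so any window that saw a
  valid pixel becomes valid, growing the known region monotonically with
  depth. Encoder kernels follow the 7, 5, 5, 3, 3, ... schedule with
  stride 2; the decoder mirrors with nearest-neighbour upsampling, skip
  concatenation and LeakyReLU(0.2); the head is a linear 3x3 convolution.
  The network, its training loop and the loss are implemented on a compact
  numpy reverse-mode autograd written for this package (float64; every op
  is finite-difference-checked in the tests). Two simplifications relative
  to the full-scale original: no normalization layers (the desk-scale nets
  trained here from scratch neither need nor could stabilize batch
  statistics at batch size 4), and decoder masks take the union of the
  skip and upsampled masks rather than carrying per-channel-group masks.
  The loss is `L_valid + w_hole*L_hole + 0.1*L_TV + 0.05*L_perc +
  120*L_style`, with the perceptual and style (Gram-matrix) terms computed
  in the fixed feature hierarchy below; `w_hole` defaults to 6 (the
  printed rendering of this weight in the source method is ambiguous, so
  it is a config parameter). Optimizer: Adam, lr 5e-4 (fine-tuning
  9.5e-5). Training at desk scale (64x64 images, ~10^2 steps) is validated
  by held-out hole-region MSE decreasing from initialization.
* **Harmonic** — solves the Laplace equation over the hole with Dirichlet
  boundary values (sparse 5-point solve); exact for affine luminance.
  Boundary-local by construction: it cannot exploit context beyond the
  hole rim, which is why the end-stopping experiment's "some context" and
  "full context" conditions nearly tie under it.
* **Mean fill** — hole replaced by the mean of the known pixels.
* **Directional** — classical structure propagation: the dominant
  coherence orientation of the surround is estimated from the structure
  tensor (eigenvector of the smaller eigenvalue), and each hole pixel is
  linearly interpolated between the known pixels met along that direction.
  It continues oriented patterns (gratings) through the hole exactly, and
  stands in for a trained model wherever the analysis needs a
  structure-completing reconstruction.

All inpainters composite: pixels outside the hole are returned
bit-identical to the input.

### Feature hierarchy

The comparison space is a fixed five-stage CNN at desk scale. Stage 1 is a
bank of quadrature Gabor pairs combined into phase-invariant oriented
energy — complex-cell-like, so the lowest level represents local
orientation and scale rather than raw phase. Stages 2-5 are strided random
convolutions whose kernels are mean-subtracted (band-pass-like) with ReLU;
zero-mean kernels make deep stages blind to spatially homogeneous inputs
and responsive to spatial structure, so depth tracks abstraction
(arrangement and texture) rather than repeated copies of channel identity.
Weights are random with a fixed seed: the metric's contract is a fixed,
hierarchical feature space with growing receptive fields, not particular
learned filters, and the extractor is pluggable so learned weights can be
substituted. Without the energy front end and zero-mean deep kernels, the
orientation of a pattern dominates the distance at every level and
low/high-level prediction failures cannot dissociate.

### Parametric-stimulus validations

* **End-stopping**: a horizontal striped bar (stripe period 24 px, stripe
  luminances 0.55/0.95 on a 0.35 background so the bar carries net
  contrast) confined to the central RF circle, extending 20% beyond it, or
  spanning the 384x384 image. With the harmonic inpainter, per-level
  unpredictability normalized by the per-level maximum is monotone
  non-increasing from no context to full context. Some/full tie because
  the bar already crosses the hole boundary in the "some" condition and a
  boundary-local inpainter sees identical Dirichlet data.
* **Feature-level mismatch**: surround is a vertical grating (period
  16 px); the hole's ground truth is the continuous grating, an orthogonal
  grating ("shifted"), or the grating with strong, rough phase noise
  ("noisy": SD 2.5 rad, correlation scale 4 px — a genuine texture
  scramble that preserves carrier orientation). The masked input is
  identical across conditions, so the single reconstruction (directional
  inpainter: the continuous grating) is compared against each ground
  truth. Stage-1 loss is maximal for the orientation flip; stage-5 loss is
  maximal for the texture scramble; the matched condition is lowest
  everywhere. The pattern holds across extractor seeds (tested for 0-2).

## Contrast-model baseline

Two quadrature Gabor banks (contrast energy: 0.02-0.32 cpd in octave
steps; spatial coherence: 0.015-0.24 cpd; 8 orientations at pi/8; each
filter DC-corrected and paired with its quadrature partner) yield local
energy E = sqrt(F0^2 + F_{pi/2}^2), computed by FFT convolution with
reflect padding. Divisive normalization applies
`Enorm = E*max(E) / (E + max(E)*S)` per (scale, orientation) map, with S
the Gaussian-windowed coefficient of variation (SD/mean). Defaults and
their reasons:

* **Bandwidth 1.5 octaves.** At 1 octave, the 0.015 cpd filter truncated
  at 2 sigma spans ~125% of a 120-degree full-field image at any pixel
  resolution (the kernel/image ratio is resolution-independent), which is
  geometrically impossible; 1.5 octaves is inside the range reported for
  mouse V1 and fits at 2-sigma truncation. Both bandwidth and truncation
  are configurable.
* **Normalization window** SD = 2x the filter wavelength, capped at a
  quarter of the image side (a surround window larger than the image
  degenerates to a global statistic), truncated at 3 SD with reflect
  boundaries. The same window function is exposed so oracle tests compare
  the exact formula.
* **max(E)** is taken per (scale, orientation) map (whether it should be
  global across orientations is unstated; per-map is the default).

Per (unit, image), 16 regressors are summarized inside the FWHM RF mask:
CE1-5 (normalized energy averaged over RF pixels and orientations), SC1-5
(mu/sigma of the orientation-averaged coherence map over RF pixels, capped
at 50 for constant regions), CEpref (channel nearest the unit's preferred
scale/orientation), circular variance
CV = 1 - |sum_k E_k e^{2i theta_k}| / sum_k E_k over the 8 orientation
channels at the preferred scale (angle doubling handles orientation
periodicity), CE at +/-30 degrees from the preferred orientation (linear
interpolation between the 22.5-degree channels, averaged across scales),
RMS contrast (SD/mean of raw RF luminance; plain SD available), and
running speed v at the observation level.

## Rates, QC and chunking

Spikes are binned at 10 ms over the 250 ms presentation, smoothed with a
30 ms (3-bin) uniform moving average whose window shrinks at the edges (no
padding, so no pre-stimulus zeros leak in), and normalized to fold change
(FR - b)/(b + 0.5 Hz) with b the mean rate over the first 20 ms, smoothing
applied before the baseline is read. Trials with blinks or with mean eye
position beyond 2 session SDs on either axis are dropped (per-trial means;
a per-sample variant is a flag; zero SD keeps all trials). Surviving
repetitions are averaged into 5 repetition-contiguous, balanced chunks
(47 reps -> 10,10,9,9,9), so the experience split maps to chunks {0,1} vs
{3,4}. The order bin -> smooth -> normalize -> QC -> chunk is fixed;
normalizing and chunking do not commute (tested).

## Time-resolved regression

Per neuron and 10-ms bin, ordinary least squares of the fold-change
response on the intercept plus the 16 baseline regressors; the extended
model appends exactly one unpredictability column (overall or a single
level). Non-intercept columns are z-scored, so coefficients are modulation
functions in fold change per SD. Derived quantities: window sensitivity
(mean coefficient over bin centres in 75-150 ms), latency to 50% of the
positive peak (linear interpolation on the rising flank; undefined without
a positive peak), and Delta-R — the increase in shuffle-split
cross-validated correlation (10 splits, 75% training; z-scoring refit on
training rows by default, global z-scoring via flag) between predicted and
observed responses, averaged over splits per bin and then over the report
window. Splits are shared between the two models, so the difference is
paired.

**Null-referenced Delta-R.** Because one extra regressor carries an
out-of-sample overfitting penalty, raw Delta-R is centred slightly below
zero when the added column is uninformative, and a two-sided mean-zero
test on it is anticonservative under the null at any scale.
`delta_r(..., null_adjust=m)` subtracts the mean of m recomputations with
the unpredictability column permuted across observations, centring the
null at zero while leaving true effects intact (m=2 in the calibration
studies). Raw Delta-R remains the default reported metric.

## Multi-level inference

Two-stage: unit values are averaged within animal (unweighted), and
inference runs across animal means. Hypothesis tests are equal-tail
bootstrap t-tests — the observed t against the bootstrap distribution of t
over the mean-centred values, >= 10^4 resamples, add-one correction
(b+1)/(B+1) so p > 0. Confidence intervals default to the percentile
bootstrap; the parameter-recovery study uses the studentized (bootstrap-t)
interval, which is second-order accurate and measurably better calibrated
with 8 animals (the percentile interval covers a 95% target at ~90%
there).

Time-course contrasts use 1-D threshold-free cluster enhancement
(E = 0.5, H = 2) under a sign-flip permutation null with max-statistic
family-wise correction; when 2^animals does not exceed the permutation
budget the null is enumerated exhaustively. The per-bin statistic defaults
to the unstandardized across-animal mean: with a handful of animals the
df-(n-1) variance estimate is unstable, and bins with freakishly small
variance inflate a t statistic — under a strong partial effect this flags
isolated false bins in ~15-20% of runs, while the mean statistic keeps
exact weak FWER control (max-statistic exchangeability holds for any
statistic) and localizes planted effects cleanly. `stat='t'` and a
variance-regularized `stat='hat'` remain available; the threshold step for
the mean statistic adapts to the observed curve (max/50) and is held fixed
across permutations. The enhancement is brute-force-checked and the
end-to-end routine is cross-checked against an independent implementation
of the same cluster test in the test suite.

## Encoding profiles

Responses per image (chunk-averaged) are predicted from each stage of the
feature hierarchy with partial least squares (25 components, reduced with
a warning when the training set cannot support them; feature maps
average-pooled to at most 4x4 per channel to bound dimensionality), scored
by shuffle-split cross-validated correlation (10 splits, 75% training) and
normalized per unit by the maximum across stages, so units contribute
relative layer preference rather than SNR. Stage profiles are summarized
by the least-squares slope against stage index 1-5, tested across animals.

## Synthetic data: what it emulates

The generator produces a session of N stimuli x R repetitions (250 ms
back-to-back by default; the inter-trial interval is a parameter since the
source protocol does not state one), pseudo-random order per sweep,
running-speed and eye traces, per-unit Gaussian RFs with Gabor-probe
mapping trials (Poisson counts around baseline rate0), and fold-change
responses from a time-resolved linear model: truncated-Gaussian temporal
kernels (support 2.5 widths; width 18 ms) scaled so the mean coefficient
in the 75-150 ms window equals a requested value, contrast kernel peaking
at 70 ms and unpredictability at 100 ms so the predictability modulation
arrives later, a laminar multiplier on the unpredictability kernel for
superficial units, and Gaussian residuals passed through the pipeline's
3-bin moving average so generated rates share the preprocessing chain's
temporal autocorrelation. Eye contamination is injected explicitly
(blinks, and positional excursions of 5 clean trial-mean SDs, a margin
that keeps the 2-SD filter's flagging deterministic even though the
outliers inflate the session SD) and logged, giving the QC tests an exact
oracle. A raw-spike mode draws inhomogeneous Poisson spikes at
max(rate0*(1+y), 0.1 Hz).

Default study population: 8 animals x 30 units (half superficial, half
deep) with 118 images x 5 chunks = 590 observations per unit. Eight
animals is the smallest population for which the two-stage bootstrap is
meaningfully calibrated — with 2-3 animals the percentile CI degenerates
to the interval between two draws (coverage ~50%) and the add-one
equal-tail p cannot reach 0.05.

Synthetic regressor tables draw image-level features from a shared latent
factor (natural images make contrast statistics and predictability
correlated; unpredictability loads at 0.35) with per-level estimates
d1..d5 increasingly correlated with the overall estimate. The generator
makes no attempt to match natural-image statistics beyond a 1/f spectrum
for the noise images, nor any eye-movement dynamics model — so passing
recovery tests establish that the analysis chain is correct and
calibrated under its own assumptions, not that those assumptions hold for
any particular recorded dataset.

## Validation studies and problem sizes

All sizes are the package's own desk-scale choices, stated here; each
study is a pure function of its seed.

* **Parameter recovery** (8 animals x 30 units, 590 obs/unit, planted
  window coefficient 0.08): the studentized bootstrap CI covers the
  planted value, and the recovered unpredictability latency exceeds the
  contrast latency, in >= 90% of seeds (measured 57/60 and 60/60 across
  seed blocks).
* **Type-I calibration** (reduced: 8 animals x 6 units, 59 images x 2
  chunks, 200 replications): window-sensitivity and null-referenced
  Delta-R tests reject at ~3-7% at the 5% level.
* **Laminar contrast** (superficial:deep kernel ratio 2:1, residual SD
  0.5): the within-animal paired difference is positive and significant in
  >= 80% of seeds, and TFCE flags only bins inside the planted kernel
  support in >= 90% (measured 20/20 at the defaults).
* **Encoding dissociation** (6 animals x 2 units, 32 images at 128 px;
  responses from a random stage-2 readout at window amplitude 0.3 plus a
  high-level unpredictability modulation at 0.2 on d5; residual SD 0.35):
  the mean normalized encoding profile peaks at stage <= 2 while the
  across-level unpredictability-sensitivity slope is positive. The planted
  high-level amplitude is set at contrast magnitude because with 32 shared
  images the slope signal is ~0.1x the planted amplitude (it tracks the
  partial correlations of d1..d4 with d5, 0.5-0.8); the unit's known
  generative tuning feature is included as a nuisance regressor (for
  recorded units the baseline contrast features play this role).
* **RF recovery** (100 units, 13x13 probe grid at 5-degree spacing, 45
  presentations per position, SNR 5 defined as peak evoked count over the
  per-position standard error): all centres within 2 grid steps; mean
  recovered FWHM area within 10% of the true mean. Because fitting runs
  on the smoothed histogram, the smoothing kernel's variance is subtracted
  from the fitted widths by default (a 1-cell kernel otherwise inflates a
  1.5-cell-wide RF's area by ~40%). Per-unit area errors at SNR 5 spread
  ~12-24% — the information in a probe grid bounds per-unit precision.
* **Noise control** (pink-noise images, responses driven by contrast
  only): the across-animal slope of per-level unpredictability sensitivity
  is non-significant in >= 90% of runs.

## Known limitations

* The harmonic baseline cannot exploit long-range context; the trained
  UNet can, but desk-scale training (10^2 steps, tiny nets) produces
  usable, not high-fidelity, completions.
* The random-weight hierarchy orders abstraction by construction, not by
  learning; level identities (edge vs texture) are qualitative.
* Bootstrap and TFCE behaviour is validated at 8 animals; below 5 animals
  the sign-flip null is too coarse and the functions refuse to run.
* The fold-change transform is applied by the generator only through the
  residual autocorrelation; planted kernels are interpreted as
  post-preprocessing coefficients, so recovery does not test the
  spike-to-rate stage (which has its own round-trip test).
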