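# Methods

This note documents the models, estimators and numerical choices behind
`quantsim`, and what its simulation-based validation does and does not
establish.

## Imaging and camera model

A grid-SIM acquisition of one depth layer is modelled per pixel as three
expected photon counts

    lambda_i = F * (1 + m * cos(theta + (i-1) * 2*pi/3)) + B,   i = 1, 2, 3

where `F` is the in-focus photon density per frame, `B` the unmodulated
(out-of-focus plus stray) photon density, `m` ∈ (0, 1] the illumination
modulation contrast at the sample plane, and `theta` the local grid phase.
Only the 2π/3 three-phase geometry is supported; it is the minimal and by
far the most common optical-sectioning SIM protocol.

The camera is linear: `DN = round(clip(g * Poisson(lambda) +
Normal(0, sigma_read) + offset, 0, 2^bits − 1))`, with gain `g`
(DN/photon), dark `offset` (DN) and Gaussian read noise `sigma_read` (DN).
Per-pixel gain variation (PRNU), nonlinearity, dark current and EM excess
noise are out of scope; fixed-pattern *offset* structure is tolerated by
the calibration (below) but not modelled explicitly.

## Demodulation

The sectioned (in-focus) amplitude is the square-law demodulation

    I_s = (sqrt(2)/3) * sqrt[(I1−I2)^2 + (I1−I3)^2 + (I2−I3)^2]

and the wide-field image is the three-phase mean. The prefactor √2/3 makes
a pure sinusoid of amplitude `A_mod` demodulate to exactly `A_mod`; any
other prefactor convention would cancel out of the photon estimates, since
the contrast calibration uses the same demodulation (the ratio I_s/W is
convention-free only if both sides share it — a property tested
explicitly). The wide-field estimator is the *mean*, not the sum, of the
phases so that wide-field photons mean "photons per single exposure under
equivalent uniform illumination", the same semantics as the shot-noise
photon counter below.

## Calibration 1: photon transfer (gain, offset, read noise)

Inputs: >5 illumination levels from a dark pair up to near saturation, two
uniformly illuminated frames per level.

* offset = mean of the dark pair;
* per level, mean = spatial mean of (a+b)/2 − offset, and
  variance = Var(a−b)/2 — differencing the pair cancels any static
  per-pixel structure common to both frames, leaving twice the temporal
  variance;
* levels whose raw mean exceeds 90% of full scale (configurable) are
  excluded: clipping bends the variance–mean line down and would bias the
  slope;
* a straight line variance = g·mean + σ²_read is fitted by *iteratively
  variance-weighted* least squares (weights 1/fitted-variance², two
  reweighting passes from an unweighted start). The weighting matters: the
  sampling error of a spatial variance estimate is proportional to the
  variance itself (sd ≈ v·√(2/n)), so in an unweighted fit the brightest
  levels — absolutely the noisiest points — dominate the intercept, and a
  read-noise variance of a few DN² is unrecoverable. With the weighting,
  both the slope and the intercept are recovered to a few percent under
  the default simulation (50/50 seeded series within 2% on gain and 15% on
  read-noise variance, for g ∈ {0.5, 2, 5}). Exact linear input is
  reproduced exactly. A negative fitted intercept is clamped to zero with
  a warning; a non-positive slope is a calibration failure.

The simulator's default illumination ladder is a dark level plus a
geometric ramp (2.2 decades) ending at 80% of full scale — the standard
photon-transfer practice, because low levels carry essentially all the
information about the read-noise intercept while the top levels pin the
slope.

The classic shot-noise photon counter `N = (mean/sigma)²` for a uniform
field is provided as an independent cross-check; it is gain-free because
mean = gN and variance = g²N.

## Calibration 2: modulation contrast

For a thin fluorescent layer (beads smaller than the sectioning thickness,
negligible out-of-focus light, `B ≈ 0`), I_s/W = m identically. The
estimator offset-subtracts the raw bead triplet, demodulates, selects
bright pixels (wide-field intensity at or above the 95th percentile, and
above a significance floor of 10× the photon-equivalent read noise so a
dark field raises an error instead of "selecting" noise), and reports the
*median* of I_s/W over the selection — median rather than mean for
robustness to bead-edge and overlap outliers. `m` is a single scalar per
objective/grid combination, stored in the calibration file.

Uniform background biases this ratio (and therefore `m̂`) downward by
roughly F/(F+B) — which is exactly why the protocol demands a thin sample;
the effect is verified as a monotone decrease of `m̂` with added
background.

## Reconstruction to photons

Each phase is converted to photons as `(DN − offset)/g`; sub-dark values go
negative and are retained (clamping would bias dim pixels upward). Then,
per pixel:

* wide-field photons `W = (N1+N2+N3)/3` → estimates `F + B`;
* sectioned photons `S/m` → estimates `F`, where `S` is the modulation
  amplitude estimate below.

### Shot-noise bias correction of the sectioned image

The demodulation is nonlinear, and at photon-counting levels its noise
bias is not negligible. Writing the modulation power `P_plain = (2/9) D`
(the square of the plain demodulation, with `D` the sum of pairwise squared
differences), per-phase noise with variances `v_i = max(N_i, 0) +
σ²_read/g²` inflates it: `E[P_plain] = A_mod² + (4/9)(v1+v2+v3)`. The
default estimator therefore:

1. debiases the power: `P = P_plain − (4/9)(v1+v2+v3)`;
2. propagates the per-phase variances to the power:
   `Var(P) = (16/81) Σ_i (2I_i − I_j − I_k)² v_i`;
3. takes `S = sqrt(max(P, 0)) + Var(P) / (8 · max(P, sqrt(Var(P)))^{3/2})`,
   the square root with its second-order (concavity) Taylor correction,
   floored at the power-noise scale so low-signal pixels stay finite.

In 2000-replicate ensembles at F = 200 photons, m = 0.5, this keeps the
ensemble-mean sectioned image within ~0.4% of F for backgrounds up to
B = 800, where the uncorrected estimator is ~3% high; the residual bias
grows once the power signal-to-noise `A_mod²/sd(P)` drops below about 1
(roughly `F·m² ≲ (8/3)·(F+B)/F`, a regime where the in-focus signal is
barely detectable anyway).

On *noiseless* input the correction subtracts variance that is not there
(the plug-in `v_i` cannot know the data are deterministic), so
`bias_corrected=False` switches to the plain demodulation, which is exact
on noiseless sinusoids. The final sectioned image is clamped at zero;
intermediate quantities are not.

### Noise maps

* Wide-field: `sigma_W = sqrt[(v1+v2+v3)/9]` — the exact standard deviation
  of a mean of three frames. Read noise is included; with the default
  camera it contributes ~1 photon² per frame.
* Sectioned: delta-method through the demodulation,
  `sigma_S = sqrt(Var(P)) / (2 · max(S, Var(P)^{1/4})) / m`, with the same
  `S` the sectioned image reports. Where the modulation power is
  numerically zero the closed-form phase-averaged limit
  `Var(I_s) = (2/3)·(mean photon count + read variance)` is substituted
  instead of a singular derivative.

Against 2000-replicate Monte-Carlo ensembles the predicted maps sit within
a few percent (median) of the empirical standard deviations for pixels
with F ≥ 50. Two qualitative properties follow from the formulas and are
asserted in tests: sectioned noise strictly increases with background at
fixed F (out-of-focus light is subtracted but its shot noise is not), and
strictly decreases with m at fixed data (the 1/m demodulation gain), and
for sinusoidal scenes sectioned noise ≥ wide-field noise whenever m ≤ 1.

## Synthetic data and the Monte-Carlo oracle

The simulator renders all three input kinds with known ground truth:
flat-field pair series, Gaussian-spot bead fields (uniformly random
positions, background 0 by default per the thin-sample assumption), and
per-depth SIM triplets/stacks under the camera model above. Design points:

* the grid is a one-dimensional sinusoid along the column axis (period
  8 px by default); orientation is irrelevant to the per-pixel algorithms;
* out-of-focus light is injected directly as the unmodulated `B` term
  rather than via 3-D PSF convolution — the reconstruction distinguishes
  only modulated vs unmodulated light, so this is the minimal faithful
  model. How contrast decays with defocus is **not** modelled;
* rounding and clipping are part of the default camera so calibration sees
  realistic quantization (the dark-pair variance includes the 1/12 DN²
  quantization term, a ~2% effect on the default read noise); `noiseless`
  bypasses Poisson, Gaussian *and* quantization for exactness tests;
* one master seed; every frame/page/replicate draws from an independent
  `numpy.random.SeedSequence`-spawned stream, so outputs are
  bit-reproducible and ensembles are honestly independent.

The `monte_carlo_oracle` renders n independent realizations of a scene,
reconstructs each, and returns per-pixel ensemble means and standard
deviations of all four outputs; it is the correctness anchor for the noise
maps (variance accumulation is done relative to a per-pixel baseline to
avoid catastrophic cancellation).

Because the simulator omits PSF structure, stripe artifacts from grid
imperfections, photobleaching across depths and stage drift, passing tests
demonstrate the *statistical* correctness of the estimators under the
stated model — not robustness to those instrument effects.

## Problem sizes used in validation

Flat-field recovery uses 8 levels of paired 512×512 frames, 50 seeded
series per gain setting; contrast recovery uses 200 beads (peak 2000
photons, σ 1.2 px) in 256×256 frames over 20 seeds; ensemble checks use
2000 replicates of 24×32–48×48 scenes; the end-to-end 3D run uses five
64×96 depths. These sizes put Monte-Carlo standard errors comfortably
below the tolerances being asserted.

## File formats

Inputs are greyscale TIFFs (8–16 bit) with the three phases concatenated
row-wise (3M×N), multi-page for 3D; RGB input is rejected rather than
silently converted. Outputs are 32-bit float TIFFs — integer grey levels
cannot carry sub-photon noise values — tagged "pixel unit: photons", plus
a YAML manifest with the calibration digest and depth table. The
calibration file is versioned, human-readable YAML holding the four
numbers (g, offset, read-noise variance, m) at full precision plus
provenance metadata; unknown schema versions and missing fields are hard
errors, never silent fallbacks. Histograms export as tab-delimited text.

## Known limitations

* The bias correction's plug-in variances assume Poisson + Gaussian read
  noise through a linear camera; strong clipping or nonlinearity violates
  it (near-saturation pixels should not be trusted quantitatively).
* `m` is global; field-dependent contrast (vignetting, grid defocus tilt)
  is not modelled.
* Depths are reconstructed independently — no axial regularization or
  deconvolution.
* The delta-method sectioned noise is a first-order approximation; below
  F ≈ 50 photons (at the default contrast) its error grows, consistent
  with its validation window.
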