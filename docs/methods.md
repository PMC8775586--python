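# Methods

This note documents the models, estimators, numerical choices and open
design decisions behind `mouseview`, and what the synthetic-data tests do
and do not establish about real imagery.

## Preprocessing model

Raw captures are 12-bit frames in 16-bit containers. The fixed processing
order is: flat-field (vignetting) correction → 3×3 median filter →
projective registration of the UV frame onto the green frame → crop to the
in-focus, fully-valid region. Min–max normalization to [0, 1] happens at
analysis time, per channel, modelling the adaptation of the visual system
to each scene's intensity range.

- *Vignetting* (flat-field): `I_corr = I_raw · max(I_ref)/I_ref`. With a
  per-channel reference when provided, else a shared one. Quantization
  error of < 1 digital number in the raw frame is amplified by 1/v at
  vignette value v, so recovery of a clean scene is exact to 1 DN only
  after weighting by the vignette field; the pure round trip (correct,
  then re-apply the reference) is exact in floating point.
- *Median filter*: 3×3, reflect padding at the borders (the filter must
  preserve image size; reflect avoids inventing edge values). The filter is
  idempotent on piecewise-constant content; on fine texture it smooths, so
  clean-structure recovery checks compare against the median-filtered clean
  image.
- *Registration*: least-squares homography from ≥ 4 control points
  (normalized direct linear transform via scikit-image), then
  inverse-mapped bilinear resampling (nearest-neighbour available for
  exactness tests). Out-of-view pixels are tracked in a validity mask,
  never filled, and removed by the crop: the automatic crop greedily trims
  the image edge with the most invalid pixels until an all-valid rectangle
  remains.
- Coordinates are 0-based (row, col); control points are (x, y); rects are
  half-open. The angular pixel pitch (default 0.006°/px) is carried through
  unchanged — no stage ever resamples resolution.

## First-order statistics

Local contrast is the response to a Laplacian-of-Gaussian kernel sampled at
integer offsets on [−3σ, 3σ]. The sampled kernel does not sum exactly to
zero, so it is mean-subtracted; this makes the response to constant and
affine images exactly zero, at the cost of a ≤ 10⁻³-relative perturbation
of the weights. Convolution uses the valid region only (no padding), so no
synthetic edge contrast enters the fitted distributions.

The contrast-magnitude distribution is fitted by a two-parameter Weibull.
Two parameterizations are in circulation: the canonical scale–shape form
with density `(γ/β)(x/β)^{γ−1} exp(−(x/β)^γ)`, under which a larger β means
a wider distribution, and a rate form `w(x) = b γ x^{γ−1} exp(−b x^γ)`
with `b = β^{−γ}`, under which the interpretation reverses. `mouseview`
reports the canonical scale as `beta_scale` (so "larger β = higher
contrast" holds) and exposes the rate value as `printed_rate`.

Fitting is maximum likelihood on the absolute filter outputs (signed vs
absolute and MLE vs histogram regression being open choices; magnitudes +
MLE are the statistically efficient defaults). Structural zeros from flat
regions are dropped and counted. The profile likelihood reduces the problem
to a monotone scalar equation in γ, solved by Brent bisection to 1e-10;
the conditional scale has the closed form `β = (mean xᵞ)^{1/γ}`, evaluated
in log space for stability. An independent 200×200 log-grid likelihood
search agrees with the solver to grid resolution.

## Patch statistics

RMS contrast is sd/mean over a discrete disk `{dx²+dy² ≤ r²}` (default
r = 30 px, a 0.36° patch at 0.006°/px), evaluated at every centre whose
full disk is inside the image (stride 1; a stride option exists for speed).
Moments are population moments — a patch is an exhaustive pixel set —
computed from disk convolutions of the image powers (FFT-based); variance
residues below 1e-12 relative are clamped to zero so constant patches give
exactly sd = 0. Kurtosis is not excess (Gaussian ≈ 3). Entropy uses 64
uniform bins on [0, 1], log base 2 (bin width and base are otherwise
unspecified choices); empty bins contribute zero. Centres whose patch mean
is below 1e-6 are flagged invalid rather than divided.

Chromatic contrast is the pointwise UV − green difference of the two RMS
maps; its right (C > 0) and left (|C|, C < 0) tails get separate Weibull
fits, each requiring ≥ 20 values, with absent sides flagged rather than
fitted.

## Second-order statistics

The power spectrum is the plain `|FFT|²` with no window or detrending; DC
is excluded from all fits. Frequencies live in (−0.5, 0.5] cycles/px; for
even image sides the Nyquist bin is folded into the positive half, so each
axis slice has floor(N/2) points. The `b/ω^a` fit is ordinary least squares
of log10 power on log10 frequency over all positive frequencies with equal
weight per FFT bin (fit range and weighting are open choices; r² is
reported so users can restrict the range). `b` is stored as raw power
extrapolated to ω = 1 cycle/px; its log10 is the regression intercept.

The autocorrelation follows the Wiener–Khinchin route: mean-subtract,
forward transform, squared magnitude, inverse transform, divide by the
zero lag. This is the *circular* (periodic) autocorrelation implicit in the
pure-FFT computation; zero-padding to the linear estimate is available
behind a flag. The normalization to correlation coefficients (R(0,0) = 1)
makes values comparable across scenes of different variance and is flagged
in the output metadata.

## Comparisons

Per-scene parameters are compared between channels with an exact two-sided
sign test on the per-scene differences (zeros dropped and counted; < 5
informative pairs flags the result underpowered). Left vs right chromatic
parameters use a two-sided Wilcoxon rank-sum, exact by enumeration when
both groups are ≤ 10 without ties, else the tie-corrected normal
approximation. Stars are strict: ⋆ p < 0.05, ⋆⋆ p < 0.01, ⋆⋆⋆ p < 0.001.
No multiple-testing correction is applied by default, mirroring per-panel
reporting; scenes with horizontal camera elevation are excluded from the
hypothesis tests but retained for the relative-intensity profiles.

Note that the exact sign test is conservative at small n: at n = 12 the
largest rejection region below 0.05 has probability 0.039, so the
realised type-I rate of a null pipeline sits just below the nominal 5%.

## Synthetic scenes: what they emulate

The generator builds both channels of a scene from a *shared* white-noise
innovation field, shaped in the frequency domain to a target `1/ω^a` power
spectrum per channel (amplitude ∝ ω^{−a/2}, DC zeroed to avoid infinite
power, then affinely mapped to [0, 1]). Sharing the innovations makes the
channels depict one scene, as co-acquired camera pairs do; an
`independent` mode breaks the coupling for null calibration.

Two intensity modes emulate the two scene families: `bimodal_sky`
composites a bright sky plateau and darker textured ground through a
smoothed random horizon (mode separation is the silhouette-contrast knob,
settable per channel), and `skewed_ground` applies a convex remap (u³)
giving the right-skewed unimodal histograms of ground clutter. Degradations
follow the acquisition physics: shared multiplicative vignette (radial,
max 1), green-channel warp by the inverse of the UV→green homography,
linear exposure gain with 0.9 headroom at the 10 ms reference exposure,
10^−OD neutral-density attenuation of green, clip-and-floor 12-bit
quantization (clipped fractions recorded, > 0.1% raises a data-quality
warning), and salt-and-pepper impulses. One global seed fans out into
per-stage `SeedSequence` substreams so each stage is reproducible alone.

The standard *upper-field* study condition gives UV the larger mode
separation (0.7 vs 0.35, equal slopes a = 2): dark objects against a
UV-bright sky. Through the full pipeline this reproduces, by construction,
the upper-field asymmetry pattern — heavier-tailed UV contrast (smaller
γ), larger vertical spectral intercept b, higher RMS contrast, wider
horizontal autocorrelation, and a right-heavy chromatic-contrast
distribution. The *lower-field* condition instead separates the spectral
slopes (UV 3.0, green 2.0), making green the wider-contrast,
larger-intercept channel. One empirical caveat discovered while designing
these conditions: after per-channel min–max normalization, a steeper slope
*alone* widens the autocorrelation but *lowers* the fitted intercept b
(the log-log line keeps falling toward ω = 1), so "more spectral power at
comparable slope" is a contrast difference, not a slope difference — hence
the separation-based upper-field construction.

What passing these tests shows: every estimator recovers known ground
truth through the full preprocessing chain, the test statistics have their
nominal null behaviour, and the pipeline propagates constructed channel
asymmetries into the expected test directions. What they do not show: that
real scenes have these statistics. The generator's fields are near-Gaussian
within regions, its horizon is a single smooth boundary, and its intensity
mixtures are free parameters — real upper/lower-field differences must be
established on real image pairs, which the pipeline reads from 16-bit
grayscale PNGs plus a `scenes.csv` metadata table.

## Problem sizes

Defaults in tests and the acceptance script: 160²–192² px synthetic scenes
(12 per batch) with filter widths σ ∈ {5, 10} and ACF offsets (50, 0) and
(0, 50); null calibration uses 50 batches of 12 scenes at 128² with
offsets (20, 0)/(0, 20); slope recovery uses 10 fields at 512²; Weibull
recovery uses 10⁵ draws. These sizes make every statistic well-conditioned
(thousands of contrast samples per fit, hundreds of spectrum bins per
regression) while keeping a full run to seconds.

## Known limitations

- No automatic (feature-based) registration, lens-distortion model, or
  focus detection — control points and crops are inputs.
- No multitaper/Welch spectral estimation and no radial spectrum; fits are
  on the two axis slices only.
- The bundled spectral curves (sensor QE, ocular media) are synthetic
  stand-ins for measured data and are labelled as such.
- The generator makes no attempt at photorealism; it emulates statistical
  structure, not appearance.
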