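# Methods

This note documents the models, estimators and design choices behind
`lgenoise`, in the order a user meets them: the synthetic phantom that
provides test data, the diffusion-process mathematics, the four noise
axes, the Rician validation, the segmentation metrics, and the paired
statistics. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The synthetic phantom and what it does (not) emulate

Real LGE-CMR cohorts of the kind this toolkit targets are proprietary, so
every analysis here is exercised on a controlled phantom: a 128×128 slice
with an annular "myocardium" (label 1, default radii 14–44 px) containing
an angular "scar" sector (label 2), on background (label 0), rendered
piecewise-constant and corrupted by configurable noise. Defaults pin the
phantom to the operating point of the clinical setting it emulates:
myocardial intensity 0.11 on the [0, 1] scale, scar hyperintense (0.35),
background 0.04, base noise std σ₀ = 0.008, pixel spacing 1.77 mm. At
these values the myocardial SNR is ≈ 14 and the background SNR ≈ 5, i.e.
inside the regime where the Gaussian approximation to Rician magnitude
noise is defensible (see below).

Noise kinds: `gaussian` (additive white), `rician` (magnitude formation
√((s+σ₀n₁)²+(σ₀n₂)²), nonnegative without clipping), `correlated` (white
field convolved with a Gaussian kernel of std `corr_sigma` px, then
renormalised so the marginal std is again σ₀ — this decouples the
correlation axis from the magnitude axis in recovery tests),
`signal_dependent` (per-pixel std σ₀ + k·s — std, not variance, is linear
in the clean signal, matching what the slope estimator fits), and
`heavy_tailed` (Student-t with `tail_df` > 2 scaled to std σ₀). No output
clipping by default: clipping would distort the kurtosis and skewness
recoveries.

Cohorts are patient-grouped with per-patient geometry jitter (±20% radii,
±4 px centre, randomised scar sector) so the within-patient resampling
machinery has realistic structure to work on. Fixed seed ⇒ bit-identical
cohorts.

`make_paired_sources` builds the three-source study design: a REAL-like
source (mildly correlated, near-signal-independent Gaussian noise at
σ₀ = 0.008, slope 0.001, correlation kernel 1.2 px), a diffusion-like
"DM" source (matched spectrum and shape: same σ₀, slope 0.005, kernel
1.0 px, myocardium 0.12), and a GAN-like source (σ₀/√10 ⇒ ~10× less
high-frequency power, slope 0.009, kernel 0.5 px, Student-t(8) marginals
⇒ positive excess kurtosis, myocardium dimmed to 0.06). All sources share
every label mask, emulating per-slice triples conditioned on one mask.
These profiles encode the qualitative characterisation of real, diffusion
and adversarial generators this protocol was designed to separate; they
are a construction, not a fit, and the tests check ordinal statements
(DM-like closer to REAL than GAN-like), not the clinical magnitudes.

What the phantom does **not** emulate: anatomy (the annulus is not a
ventricle; its wall is deliberately wide so that edge-safe interior
regions exist — see the ROI discussion below), k-space acquisition,
coil-sensitivity maps, partial-volume blur, or the long-range noise
correlations of parallel-imaging reconstruction. Passing tests therefore
demonstrate that the *estimators* recover known injected physics and that
the *protocol* separates constructed generator archetypes; they do not
certify behaviour on any particular scanner's data.

## Diffusion-process mathematics

Timesteps are zero-based, t ∈ {0,…,T−1}; images live on [−1, 1]
(x ↦ 2x−1 from the unit scale, exact inverse provided).

- **Schedule.** Cosine schedule: ᾱ(t) ∝ cos²(((t/T + s)/(1 + s))·π/2)
  with offset s = 0.008 and β_t = 1 − ᾱ_t/ᾱ_{t−1} clipped to 0.999. At
  T = 250 this gives ᾱ₀ > 0.99 and ᾱ_{T−1} < 0.01.
- **Forward process.** Stepwise x_k = √(1−β_k)x_{k−1} + √β_k z, with the
  closed-form marginal x_t = √ᾱ_t x₀ + √(1−ᾱ_t) ε. The two agree in first
  and second moments at every t (property-tested by Monte Carlo), and the
  marginal inverts exactly: x₀ = (x_t − √(1−ᾱ_t)ε)/√ᾱ_t.
- **Reverse process.** ε-parameterisation: μ = (x_t − ((1−α_t)/√(1−ᾱ_t))
  ε̂)/√α_t; sampling step μ + √β_t z with fixed variance σ_t² = β_t and no
  stochastic term at t = 0. Conditioning concatenates the one-hot mask
  (values kept at {0,1}, not rescaled — the conditioning channels are
  indicators, not intensities) with the image into a 4×H×W input.
- **Objective.** Per-pixel ℓ1 (default) or ℓ2 noise-prediction error,
  weighted by W(i,j) = Σ_c w_c Y_c(i,j) with defaults (w_bg, w_myo,
  w_scar) = (0.2, 1.5, 3.0) and normalised by Σw + ϵ with ϵ = 10⁻⁸ (the
  stabiliser's value is a free choice; any tiny positive constant works).
- **Predictor contract.** Any callable (x̃_t, t) → ε̂ of the image's shape.
  The `OraclePredictor` returns the exact forward noise and drives reverse
  sampling onto its target to machine precision — an end-to-end identity
  check of the sampling loop. The `ToyConvPredictor` (fixed 3-filter bank
  per channel, per-time-bucket linear weights, Adam on the weighted ℓ1
  subgradient) exists to show the objective is trainable in seconds on a
  CPU; it is not a generative model of any quality.

## The four noise axes

All residual-based axes start from the Gaussian high-pass residual
r = x − G_σ·x with σ_hp = 6 px and reflective boundaries; the shared
low-frequency roll-off this induces below ≈ 0.03 cycles/px is excluded
from cross-source PSD comparisons as a pre-filter artefact, not a noise
feature.

**Mask-corrected spectra and autocorrelations.** For an ROI-restricted
field, raw lag sums and per-lag pair counts are computed by zero-padded
FFT products; dividing sum by count gives an unbiased per-lag second
moment wherever at least 32 pixel pairs contribute (fewer ⇒ the lag is
zeroed and, for the correlation integral, a support error). No mean
subtraction is applied: the input is a high-pass residual whose DC is
already removed, and raw second moments let a perfectly correlated
(constant) field report ρ ≡ 1. For the PSD, the corrected autocovariance
is multiplied by a radial Hann lag taper (half-width min(H,W)/4 px,
Blackman–Tukey style) before the FFT — without the taper, long-lag
estimation noise produces negative power bins. Power is radially binned
at 1/max(H,W) cycles/px up to Nyquist. On white noise the corrected PSD
is flat (band max/min < 3 on a single 128×128 annulus realisation) and on
a full-frame mask it matches the radially averaged periodogram.

**PSD distance.** Mean over supported bins of (log₁₀ p − log₁₀ p_ref)²,
with the reference the per-bin median over the real set's PSDs; bins with
nonpositive power in either curve are excluded. The log₁₀ convention ties
a uniform 10× power deficit to a distance of exactly 1.

**σ(μ) slope.** The ROI is tiled with non-overlapping 7×7 windows fully
inside the mask; per window, μ is the raw-image mean and σ the std
(ddof = 1) of the image minus a 1 px Gaussian blur, so smooth in-window
signal gradients do not inflate σ. The slope is the first-order
coefficient of an unweighted least-squares line σ = a + b·μ; at least 10
valid windows are required. When a label map is supplied, windows must be
label-pure with 2 px to spare: on a piecewise-constant phantom, sharp
inter-class edges (and the detrending blur's leakage across them) would
otherwise masquerade as signal-dependent noise. The detrending attenuates
the measured slope by a known factor (≈ 0.87 for white noise; more for
spatially correlated noise) — the estimator is used comparatively and for
ordinal recovery, and the injected-slope recovery test's 25% band covers
the attenuation.

**Short-range correlation.** ρ(r) from the mask-corrected autocorrelation
radially averaged into integer-lag bins 0..10 (nearest-integer
assignment), normalised to ρ(0) = 1, integrated by the trapezoidal rule:
10.0 for a perfectly correlated field, ≈ 0.5 for white noise, strictly
monotone in the phantom's correlation kernel.

**Distributional shape.** Bias-corrected sample skewness and excess
kurtosis of the residual inside the ROI (≥ 100 px, nonzero variance).

**σ̂ (wavelet-MAD).** Single-level db2 decomposition; σ̂ = median(|HH
coefficients inside the tissue mask|)/0.6745, the classical robust
estimator (an orthonormal wavelet maps white noise of std σ to HH
coefficients of std σ). The tissue mask is eroded by 2 px before mapping
to coefficient resolution so edge-straddling coefficients are excluded.
The extra-myocardial tissue mask itself is the background more than 4 px
from the myocardium, computed once per slice from the shared mask and
reused across sources so σ̂ is compared on identical support.

**Edge-safe ROI.** On a piecewise-constant phantom the σ_hp = 6 px
high-pass spreads each inter-class intensity edge over ~±2σ_hp, and at
σ₀ = 0.008 that leakage would dominate the noise everywhere in a thin
annulus — the shape axis would then measure shared structure, not noise.
`evaluate_sets` therefore runs the residual-based metrics on an edge-safe
ROI: each constituent class region eroded by 10 px (the full ROI is kept
for mean intensity, and the slope uses label-pure windows instead). This
is also why the default annulus is anatomically oversized (30 px wall):
wide enough to retain an interior after erosion. On smooth real images
the margin can be reduced via `roi_margin_px`.

**Protocol conventions.** Generated slices pair with real slices by
(patient, slice) and must share the mask bit-for-bit; scar-ROI analyses
require ≥ 100 scar pixels; every support failure is flagged per record
and counted in the exclusion report, never silently averaged over.

One known behaviour of the constructed cohort: the GAN-like source ends
slightly *above* REAL on the correlation axis (its noise is 10× weaker,
so the small shared residual leakage weighs relatively more), while its
profile alone would put it below. The protocol's ordinal claim — DM-like
closer to REAL than GAN-like on every axis median — holds either way and
is what the tests assert.

## Rician validation

Rician moments use mean = σ√(π/2)·L_{1/2}(−ν²/2σ²) and variance
2σ² + ν² − mean², with the Laguerre function evaluated through
exponentially scaled Bessel functions (`ive`), which is stable at all SNR
without an asymptotic switchover. KL(Rician ‖ moment-matched Gaussian) is
computed in nats by adaptive quadrature of p·log(p/q) over
[max(0, m−10s), m+10s]. The divergence depends on (ν, σ) only through
ν/σ; it is ≈ 8×10⁻⁴ nats at SNR 3 and < 10⁻⁶ by SNR 50, which is the
quantitative basis for treating magnitude-image noise as Gaussian in
tissue whose SNR exceeds ≈ 3. (In bits the values are smaller by ln 2;
the 10⁻³ threshold statement holds in either unit.)

## Segmentation metrics

Dice = 2TP/(2TP+FP+FN), precision = TP/(TP+FP), recall = TP/(TP+FN) from
pixel counts. Zero-denominator conventions: both masks empty ⇒ all
metrics 1 and HD95 = 0; prediction empty with nonempty truth ⇒ dice 0,
recall 0, precision undefined, HD95 undefined — undefined values are
flagged and excluded from aggregates rather than imputed. HD95 takes
boundaries as foreground pixels with ≥ 1 background 8-neighbour (the
image frame counts as background), directed distances from exact
Euclidean distance transforms scaled by the pixel spacing, the
linear-interpolation 95th percentile of each direction, and the max of
the two. It matches an O(n²) all-pairs oracle exactly on random small
masks, is translation-invariant, and scales linearly with spacing.
Per-patient aggregation pools TP/FP/FN counts across slices (overlap
metrics) and averages per-slice HD95 over slices where defined — pooling
versus averaging for the overlap metrics is a genuine convention choice;
pooling weights slices by lesion size and is recorded here as the
package's convention.

## Paired statistics

Wilcoxon signed-rank (two-sided): zero differences dropped (recorded via
n_effective), midranks for ties, W = sum of positive-difference ranks.
For n ≤ 25 the null distribution is enumerated exactly by dynamic
programming over doubled midranks (so midranks become integers); above
that, a normal approximation with the tie correction Σ(t³−t)/48 and a 0.5
continuity correction. The exact path equals 2ⁿ brute-force enumeration
for n ≤ 12 (tested), and the implementation's type-I error at nominal
0.05 lies in [0.03, 0.07] under a symmetric null (2000 simulations,
n = 20).

Rank-biserial effect size: r = (W⁺−W⁻)/(W⁺+W⁻) ∈ [−1, 1] by default,
categorised negligible/small/moderate/large at |r| ≥ 0.1/0.3/0.5
(inclusive). The variant r = 1 − 2W/(n(n+1)) sometimes seen in print is
confined to [0, 1] when W is the positive-rank sum and cannot express
direction; it is retained as `formula="as_printed"` for audit only.

Multiplicity: Bonferroni min(1, p·m) within each metric family across the
pairwise source contrasts (m = number of contrasts); Holm–Bonferroni
step-down available for other analyses and never anti-conservative
relative to Bonferroni (tested elementwise). Bootstrap CIs are percentile
intervals of the resampled mean (10,000 resamples default, seeded);
coverage on simulated normal data is near nominal (the percentile method
is known to undercover slightly at n ≈ 30). Robustness: 1000 iterations,
one random slice per patient per iteration, fraction of iterations whose
Bonferroni-corrected p < α with median-difference sign matching the
full-data sign.

## Problem sizes and numerical conventions

The test suite and acceptance script use 128×128 slices, cohorts of 12–30
patients × 3–4 slices, diffusion demos at 32×32 with T = 50, 200–300
Monte-Carlo draws for moment checks, 2000 null simulations for the type-I
check, and 200 datasets × 2000 resamples for bootstrap coverage — sizes
chosen so each recovery's Monte-Carlo tolerance (generally 3/√N) is well
inside the asserted band while the whole suite runs in well under a
minute. Crops use half-open, 0-based windows with floor(x+0.5) centroid
rounding; constant slices are rejected by the normaliser rather than
mapped to zero (silent zeros would poison σ̂ downstream); reports embed
the seed and a config hash, and all pipelines are pure functions of
(inputs, config).

## Known limitations

- The phantom's correlated-noise mode is a stand-in, not a scanner model;
  no claim is made about any specific reconstruction pipeline.
- The σ(μ) slope is attenuated by the detrending blur in a
  correlation-dependent way; it is an ordinal/comparative instrument, not
  an unbiased estimator of the injected coefficient.
- The denoiser is a contract, not a model: nothing here trains or
  evaluates a full U-Net generator.
- Per-patient overlap pooling and the HD95 aggregation (mean of per-slice
  values) are conventions; alternatives exist and would change absolute
  numbers.
- All analyses are 2D and single-channel; volumetric noise structure and
  multi-coil (non-central chi) statistics are out of scope.
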