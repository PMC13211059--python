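# lgenoise

Noise-fidelity evaluation for mask-conditioned generative cardiac MR
synthesis — plus the diffusion-process mathematics, segmentation metrics and
paired statistics that such an evaluation sits on.

## The problem

Generative models (diffusion models, GANs) are increasingly used to
synthesise late-gadolinium-enhancement cardiac MR (LGE-CMR) slices from
three-class label maps (background, myocardium, scar) for training-set
augmentation. Whether the synthetic images help a downstream segmenter
depends not only on anatomy but on whether the generator reproduces the
*scanner's noise statistics*: its spectral content, its (near-absent)
signal dependence, its short-range spatial correlation, and its
distributional shape. `lgenoise` implements a four-axis protocol that
quantifies each of those properties per slice, compares paired image sets
(real vs. each generator, all sharing the ground-truth mask) with Wilcoxon
signed-rank tests, rank-biserial effect sizes r, Bonferroni correction
within each metric family, and a within-patient resampling robustness check
against pseudoreplication.

The four axes, per slice and ROI:

1. **Spectral content** — mask-autocorrelation-corrected radial power
   spectral density of the Gaussian high-pass residual (σ = 6 px),
   summarised as the mean-squared log₁₀-PSD distance to the real set's
   median curve.
2. **Signal-dependent variance** — slope b of σ = a + b·μ over 7×7
   windowed local statistics, with the local σ taken on a detrended
   residual (σ near 0 for signal-independent Gaussian noise).
3. **Short-range spatial correlation** — ∫₀¹⁰ ρ(r) dr of the normalised,
   mask-corrected radial autocorrelation of the high-pass residual
   (0.5 for white noise, 10 for a perfectly correlated field).
4. **Distributional shape** — excess kurtosis and skewness of the
   high-pass residual (0 for Gaussian noise).

Supporting machinery, each its own module:

- `phantom` — a synthetic cardiac phantom (annular myocardium, angular scar
  sector) with controlled noise physics: Gaussian, Rician magnitude
  formation √((s+σn₁)² + (σn₂)²), spatially correlated, signal-dependent
  (σ(s) = σ₀ + k·s), and heavy-tailed Student-t noise, grouped into
  patients. It stands in for the proprietary clinical cohorts this class of
  analysis targets.
- `diffusion` — mask-conditioned DDPM process mathematics: cosine schedule
  (T = 250 default), forward marginal x_t = √ᾱ_t·x₀ + √(1−ᾱ_t)·ε, exact
  inversion, ε-parameterised reverse mean and sampling step (σ_t² = β_t,
  no noise at t = 0), conditioning by channel concatenation with the
  one-hot mask, the normalised spatially weighted ℓ1 objective
  L = Σ wᵢℓᵢ / (Σ wᵢ + ϵ) with class weights (0.2, 1.5, 3.0), and
  parameter EMA (decay 0.995) — all against a pluggable noise-predictor
  contract (an oracle predictor and a small trainable one are included;
  a full U-Net is out of scope).
- `rician` — validates the Gaussian approximation to Rician magnitude
  noise: KL(Rician(ν,σ) ‖ moment-matched Gaussian) as a function of
  SNR = ν/σ; the divergence falls below 10⁻³ nats above SNR ≈ 3.
- `segmetrics` — Dice = 2TP/(2TP+FP+FN), precision, recall, and the
  95th-percentile Hausdorff distance in mm, with per-patient pooling.
- `paired_stats` — exact (n ≤ 25) and tie-corrected approximate Wilcoxon
  signed-rank, rank-biserial r = (W⁺−W⁻)/(W⁺+W⁻) with the
  0.1/0.3/0.5 effect-size categories, Bonferroni and Holm–Bonferroni,
  percentile bootstrap CIs (10,000 resamples), and one-slice-per-patient
  resampling robustness (1000 iterations).

## Worked example

Build a paired synthetic cohort — a REAL-like source at the cohort
operating point (myocardial mean 0.11, noise σ ≈ 0.008 on the [0,1] scale),
a diffusion-like source with matched noise, and a GAN-like source with a
~10× high-frequency power deficit, dimmed myocardium (0.06), heavy tails
and a steep σ(μ) slope — then run the full protocol:

```python
from lgenoise import phantom, pipeline

sources = phantom.make_paired_sources(n_patients=12, slices_per_patient=4, seed=0)
real = sources.pop("REAL")
cfg = pipeline.RunConfig(seed=0, n_robust_iter=200)
bundle = pipeline.run_noisefid_pipeline(real, sources, cfg)
print(bundle["summary_medians"][["psd_distance", "sigma_mu_slope",
                                 "short_range_corr", "hp_kurtosis"]].round(4))
```

```
        psd_distance  sigma_mu_slope  short_range_corr  hp_kurtosis
source
DM            0.0689          0.0019            2.9187       0.7348
GAN           0.2743          0.0070            4.3413       3.7897
REAL          0.0569          0.0003            3.3879       0.7042
```

The DM-like source sits closer to REAL than the GAN-like source on every
axis: its PSD distance is at the real set's own spread (0.069 vs. 0.057)
while GAN's is ~4× larger; its σ(μ) slope and kurtosis are near REAL's
while GAN's are several-fold off. The per-contrast table quantifies this:

```
print(bundle["contrasts"].query("contrast == 'DM-vs-GAN'")
      [["metric", "p_corrected", "r_rb", "effect_category", "robustness_fraction"]])
```

```
          metric  contrast  p_corrected     r_rb effect_category  robustness_fraction
    psd_distance DM-vs-GAN 5.050745e-09 1.000000           large                  1.0
     hp_kurtosis DM-vs-GAN 5.381174e-09 0.998299           large                  1.0
```

i.e. the DM-vs-GAN contrast on the spectral and distributional axes is a
large effect (|r| ≈ 1), significant after Bonferroni correction within the
metric family, and survives 100% of one-slice-per-patient resamples.

A CLI mirrors the library: `lgenoise phantom generate`, `lgenoise noisefid
run`, `lgenoise ricianval curve`, `lgenoise segeval`, `lgenoise stats
contrast`, `lgenoise diffusion demo`.

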