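# Methods

This note documents the models, conventions and design choices behind
`scenedegrade`, in the spirit of the methods documentation of packages such
as `statsmodels` or `msprime`: what is computed, under which assumptions,
and where the genuinely open choices were resolved.

## Frequency-domain conventions

All operators work on the 2-D DFT of a 0–255 float image, using the
unnormalized forward / 1-over-N inverse convention (`numpy.fft`). Under
this convention the amplitude at the zero-frequency bin equals
`H·W·mean(image)`, and Parseval's identity reads
`sum(x²) = sum(|X|²)/(H·W)`.

Radial frequency is expressed in **cycles per image (cpi)**: per-axis
frequencies in cycles per pixel (`u/W`, `v/H`) are combined isotropically
in pixel space and scaled by the image height `H`. The Nyquist frequency is
`H/2` cpi and corner bins reach `(H/2)·√2`. Cycles per degree of visual
angle are `cpi / vertical_extent_deg`; at the reference display geometry (431×323-px
pictures spanning 11.6° of visual angle vertically) this reproduces all eight printed
display cutoffs — e.g. 120.68 cpi → 10.40 cpd and 64 cpi → 5.52 cpd — which
is why this particular cpi convention was adopted for non-square images.

Color images are processed per channel with the identical frequency-domain
operation; stochastic operators draw one noise-phase field per stimulus and
share it across channels, so chromatic structure is displaced coherently.
Luminance statistics (mean/SD) are computed on the per-pixel channel mean.

## Degradation operators

**Band filters.** A low- or high-pass filter is parameterized by its
full-attenuation frequency `F1`; the passband edge `F0` sits exactly three
octaves inside (`F0 = F1/8` low-pass, `F0 = 8·F1` high-pass). Between the
two, amplitude gain falls parabolically *in octaves*:
`gain = 1 − (x/3)²` with `x = |log2(f/F0)|`. This is 1 at `F0`, 0.75 half
way (1.5 octaves) and 0 at `F1`. The parabola orientation is a package
choice — the falloff is described as parabolic but no formula is fixed by
the source material — and is isolated in `filter_gain` so it can be
swapped. The DC bin is always passed: every degraded stimulus is
renormalized afterwards, and a zeroed mean only destabilizes the rescale.
A filter whose `F1` exceeds the corner frequency of the grid (possible for
the high-pass grid on small images) wipes out all structure; the resulting
stimulus is a blank mid-gray picture, not an error.

**Phase scrambling** uses the weighted-mean-phase construction: the new
phase at each bin is the argument of `(1−w)·e^{iφ} + w·e^{iφ_n}`, where the
noise phase field `φ_n` is the phase spectrum of white Gaussian noise —
uniform on (−π, π] at every free bin, with Hermitian antisymmetry and
correct self-conjugate bins by construction. The amplitude spectrum is kept
bit-exactly; `w = 0` reproduces the input and `w = 1` keeps only noise
phase. If the two phasors cancel exactly (a measure-zero event at
`w = 0.5`), the noise phase is used.

**Whitening** multiplies the amplitude spectrum by
`W(f) = (f/f_N)·exp(1 − (f/f_N)⁴)`, rising linearly with radial frequency
through the natural-image passband and rolling off smoothly near the
Nyquist frequency `f_N` to avoid amplifying corner-frequency noise. On a
1/f spectrum the product leaves a residual log–log slope of `−4(f/f_N)⁴`,
about −0.06 when averaged over 0.1–0.6 `f_N` — flat to within the ±0.15
band the test suite enforces. The analytic form of the guard is a package
choice and lives in `whitening_gain`. The DC gain is 1 (mean preserved).

**Renormalization.** Degraded stimuli are stretched linearly to span the
full 0–255 range; the base picture set is standardized to mean 128 /
SD 72.11 (clipped at the display limits — the targets are met exactly
whenever no pixel clips). Degradation runs in float; quantization to 8 bits
happens only on PNG write, so analyses can run pre-quantization.

**Level grids.** The packaged presets are the grids of the reference two-alternative categorization design: 4 levels per
condition for human observers (high-pass F1 120.68/85.33/60.34/10.67 cpi,
low-pass 5.66/9.19/14.93/64 cpi, phase weight 70/65/60/40 %) and 15 levels
per condition for artificial classifiers, of which the 4 human levels are a
subset. Enumerating 576 pictures × 3 degradations × 15 levels yields the
25,920 predictions of the full test design.

## Psychometric model

Accuracy as a function of stimulus *clarity* x is modeled by a Weibull
function

    ψ(x) = γ + (1 − γ − λ)·(1 − exp(−(x/α)^β)),

with guess rate γ fixed at 0.5 (two-alternative task) and lapse rate λ free
but capped at 0.05, following the standard treatment of lapses in
psychometric fitting. α (scale) and β (slope) are estimated by maximizing
the Bernoulli log-likelihood with L-BFGS-B over (log α, log β, λ), analytic
gradients, and a small multistart grid over initial scales and slopes.

Each degradation axis is first mapped onto a clarity axis along which
accuracy increases: the low-pass cutoff itself (cpi), the reciprocal of the
high-pass cutoff, and the retained phase proportion `1 − w`. Fits are
performed on **linear clarity** for all three kinds. Fitting the filters on
log-clarity was considered and rejected: the high-pass clarity axis maps
levels into (0, 1), where logs are negative and the Weibull is undefined,
and the Weibull is in any case already sigmoidal in log x (the Quick
parameterization), so log-spaced level grids are handled naturally. The
axis is recorded in the fit metadata.

The 80% threshold is solved in closed form,
`x₀.₈ = α·(−ln(1 − q))^{1/β}` with `q = (0.8 − γ)/(1 − γ − λ)`, and mapped
back through the clarity-axis inverse to original units.

Degenerate data — accuracy at ceiling or at chance at every level, or a
fitted scale escaping the tested range by more than a factor of 8 — yield
`converged = False` and an out-of-range threshold rather than a spurious
estimate.

**Bootstrap.** Confidence intervals are parametric ("coin-flip") bootstrap:
each of `n_boot` (default 2000) replicates redraws every level's correct
count from a binomial with the fitted curve's probability and the original
per-level n, refits warm-started at the point estimate, and records the
threshold; the interval is the 2.5th/97.5th percentile. Replicates that
fail to refit are dropped and counted, and the interval is flagged when
more than 10% fail. In simulation (200 datasets, 160 trials/level, 8
levels, n_boot = 500) the interval covers the generating threshold ≈95% of
the time; the test suite recomputes this.

## Comparison statistics

Accuracies of an artificial classifier (c) and human observers (h) at a
matched degradation level are compared as the ratio
`R = (k_c/n_c)/(k_h/n_h)` with the Katz log method:
`SE(ln R) = √(1/k_c − 1/n_c + 1/k_h − 1/n_h)`, 95% CI
`exp(ln R ± 1.96·SE)`, two-sided p from the normal deviate. Zero cells
receive the Haldane–Anscombe +0.5 correction to all four counts before the
log method. p-values are Bonferroni-corrected for the four matched levels
per degradation type by default.

Image-level agreement compares the observed proportion of matching
decisions to the chance agreement implied by the two accuracies,
`E = a_c·a_h + (1−a_c)(1−a_h)` (accuracy product plus error product), as
the ratio `O/E`. Inference uses the same log-ratio machinery: the observed
agreement is a binomial proportion over the compared images, the variance
of ln E is propagated from the two accuracy proportions by the delta method
(`∂E/∂a_c = 2a_h − 1`, `∂E/∂a_h = 2a_c − 1`), and the two log-variances are
added (the O–E covariance is neglected, which in the null simulations below
makes the interval mildly conservative). When both systems approach
ceiling, E → 1 and the ratio is pinned near 1 — agreement on a trivial task
carries no information, and the statistic reflects that by construction.

Calibration, recomputed by the test suite and the acceptance script: under
equal true accuracies the ratio test rejects at ≈4–5% nominal 5%; under
conditionally independent simulated observers the agreement-ratio CI
contains 1 in ≥90% of runs; a shared per-image difficulty
(`d_i ~ N(0, 1)` multiplying both observers' clarity by `e^{d_i}` at
mid-range accuracy) drives the ratio significantly above 1.

In pipeline reports, human counts pool all observers' trials at a
condition; observed agreement is computed per observer against the
classifier and averaged, while the pooled counts drive the inference.

Classifier score grids (stimulus × run, values in [0, 1]) are reduced by
rounding each score half-up to a binary decision; group accuracy is the
mean of per-run accuracies, and the group image-level decision is the
majority vote with ties resolved by rounding the mean score.

## Synthetic data

The generator replaces real photographs, human participants and fine-tuned
networks with stand-ins that have the statistical structure the analysis
assumes — no more.

* **Pink images**: amplitude ∝ f^(−slope) (slope 1 by default, the 1/f
  regime of natural scenes) with uniform random Hermitian phase,
  standardized to mean 128 / SD 72.11. Default geometry 323×431 px,
  the package's reference picture size. The radially averaged log–log amplitude
  slope measures −1.0 ± 0.15 across seeds.
* **Two object classes** on the pink background: the "animal" surrogate
  adds clusters of smooth anisotropic Gaussian blobs (low-frequency
  energy); the "vehicle" surrogate adds sharp axis-aligned rectangles plus
  a fine square-wave grating at a 4–6-px period (high-frequency,
  cardinal-orientation energy). `class_signal` (default 60 on the 0–255
  scale) sets the structure amplitude relative to the background. A simple
  high/low band-power ratio separates the classes with AUC > 0.9 at the
  default signal and falls to chance at `class_signal = 0`. These classes
  are separable *by amplitude statistics alone*, unlike real
  animal/vehicle photographs — see Limitations.
* **Simulated observers** draw per-trial correctness from the same Weibull
  model the fitting module estimates, with per-kind α and β. Paired
  observers share a latent per-image difficulty `d_i ~ N(0, sd)` that
  multiplies both effective clarities by `e^{d_i}`; `sd = 0` gives
  conditionally independent errors (the agreement-ratio null), large `sd`
  induces image-level error correlation (the power case).
* **The stand-in classifier** is a regularized logistic model on
  adjacent-band log-energy ratios (7 log-spaced radial bands between 0.06
  and 1.0 Nyquist) plus a cardinal-to-oblique orientation-energy ratio
  above 0.1 Nyquist. Band *ratios* rather than raw band energies make the
  features invariant to gain shared across a band pair, so the model's
  accuracy degrades gradually as filtering empties parts of the spectrum
  instead of collapsing on the first out-of-distribution stimulus. Swept
  across the 15-level grids it produces monotone accuracy-vs-clarity
  functions for each degradation kind.
* **Crop augmentation** produces ten 80% crops on a fixed 2×5 raster:
  vertical offsets 0 and 10% of height, horizontal offsets 0/5/10/15/20% of
  width. The raster is a package choice fixed for determinism; the
  horizontal step was only loosely constrained by the source procedure.

All randomness flows from a single master seed through named
`SeedSequence` substreams (image generation, per-stimulus phase fields,
observers, bootstrap), so every artifact is reproducible bit-for-bit.

## Pipeline

`run_pipeline` executes generate → degrade → classify/simulate → fit →
compare under one `RunConfig` and stamps every output table with the config
hash and seed; identical configs give byte-identical CSVs. Even-indexed
images train the classifier, odd-indexed images are degraded and tested.
Simulated humans (default 4, with 8% log-normal between-observer
sensitivity jitter around scales whose 80% thresholds fall inside the
4-level grids) answer every degraded stimulus, aligned with the classifier
by stimulus id so that image-level agreement is well defined.

## Problem sizes

The test suite and acceptance script run the statistical machinery at desk
scale, chosen to keep each check tight but affordable: threshold recovery
at 2000 trials/level over 8 levels; bootstrap coverage over 200 simulated
datasets at 160 trials/level and 500 bootstrap replicates; type-I error
over 1000 simulated pairs at n = 500; agreement calibration over 50–100
runs of 2000 images; the end-to-end sweep on 161×215-px images with 16
training and 16 test images per run across all 45 degradation conditions.

## Limitations

* The synthetic classes are separable by second-order (amplitude)
  statistics, so the stand-in classifier survives full phase scrambling at
  ceiling accuracy — real animal/vehicle categorization collapses there.
  Passing end-to-end tests therefore demonstrates that the machinery is
  wired correctly, not that real photographs would yield these curves.
* The Weibull lapse cap (0.05) and the fixed guess rate are modeling
  choices; observers with asymmetric response biases are not modeled (the
  simulated decision is derived from correctness, not from a signal-
  detection model).
* Agreement-ratio inference neglects the observed–expected covariance;
  null simulations show the resulting interval is conservative rather than
  anti-conservative at the accuracies exercised here.
* The Koopman score interval, cited as an alternative to the Katz log
  method, is not implemented; the `accuracy_ratio` surface is the hook
  where it would go.
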