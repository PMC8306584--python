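# Methods

## Pipeline overview

The analysis takes per-subject serum Raman spectra (wavenumber vs
intensity) with a binary CD / non-CD label and produces, per diagnostic
marker, an ROC curve with AUC and 95% interval, a Youden-optimal cutoff,
and sensitivity/specificity with exact binomial intervals. Four stages:
window extraction, Gaussian deconvolution, Phe normalization, ROC
evaluation. Each stage is usable alone (functions and sklearn-style
estimators) or through the `ramancd` CLI.

## Synthetic cohort model

No patient sera are distributed, so cohorts are simulated. A subject's
spectrum on the grid ν ∈ [400, 3100] cm⁻¹ (step 1.9285 cm⁻¹) is

I(ν) = b(ν) + Σᵢ aᵢ exp(−(ν − cᵢ)² / 2σᵢ²) + ε(ν)

* **Band library** — ten Gaussian components at the main serum bands
  (520 disulfide, 759 tryptophan, 830/850 tyrosine doublet, 1003 Phe,
  1300 amide III, 1450 CH₂ scissoring, 1550 amide II, 1650 amide I,
  2935 C–H stretch; the tyrosine doublet is one assignment but two
  physical peaks). Widths σ ∈ [4, 12] cm⁻¹ and relative amplitudes are
  fixed conventions chosen to resemble a serum spectrum's proportions;
  the Phe band is narrow (σ = 4) and strong, as an internal standard
  should be.
* **Inter-subject variation** — each amplitude aᵢ is log-normal with
  mean amplitude and CV 0.12 (log-normal keeps intensities positive; a
  ~12% biological CV is a realistic serum protein-level variation). The
  disease effect multiplies the mean of the 1650 and 1450 bands by 2.0
  for CD subjects and leaves every other band, including the Phe
  standard, untouched.
* **Baseline** — a gentle quadratic b(ν) = 0.1 − 3·10⁻⁵ν + 5·10⁻⁹ν²
  (≈ 0.05–0.09 intensity units across the grid) standing in for residual
  fluorescence. It is deliberately small relative to the bands: the
  downstream fit follows the no-baseline-correction convention, so any
  background it cannot attribute to a band is folded into band areas as
  a class-independent offset that dilutes the multiplicative disease
  effect. With the default amplitudes the dilution is modest and the
  default cohort separates with AUC ≈ 0.97–1.0, the regime the method
  is intended to demonstrate.
* **Noise** — i.i.d. Gaussian per grid point with SD
  noise_sd/√n_exposures (defaults 0.05 and 32), the variance reduction
  of averaging repeated exposures.
* **Determinism** — subject i draws from `default_rng(seed + i)`, so a
  cohort can be extended without reshuffling existing subjects.
  Defaults: 21 CD, 27 non-CD.

What the simulator does **not** emulate: Lorentzian/Voigt line shapes,
cosmic-ray spikes, detector response, wavenumber miscalibration,
correlated (pink) noise, and strong curved fluorescence backgrounds.
Passing tests therefore demonstrate the correctness and internal
consistency of the analysis machinery under its own assumptions, not
clinical performance on real sera.

## Deconvolution

Windows: amide I 1550–1750, CH₂ 1400–1500, Phe 990–1015 cm⁻¹ (each must
cover ≥ 8 grid points). Per window, a k-component Gaussian mixture is
fitted by trust-region-reflective least squares (analytic Jacobian, ftol
10⁻¹⁰, xtol 10⁻⁹, max 2000 iterations) with **no baseline term**; raw
intensities are fitted as-is. Defaults k = 4 (amide I), 3 (CH₂), 1
(Phe); the band area — the only quantity used downstream — is weakly
sensitive to k on smooth bands, and k is overridable per window.

Starting values: centers at the k most prominent local maxima (ties
broken toward lower wavenumber; missing maxima filled by uniform spread),
amplitudes at the local intensity, σ₀ = width/(4k).

Bounds: amplitudes ∈ [0, 1.5·max|y|], σ ∈ [grid step, width/2], centers
allowed to drift ≤ 10% of the window width beyond its edges. The
amplitude cap and the σ cap at half the window width both exist for the
same reason: the reported area is the analytic integral over (−∞, ∞), so
a component essentially invisible inside the window — a needle centered
in the out-of-window margin, or a quasi-flat component much wider than
the window — can carry arbitrarily large area that the data never
constrain. Bounding both keeps the analytic area identified by the
observed signal. Non-convergence is reported as `converged=False` (never
an exception); `band_area` refuses unconverged fits so silent failures
cannot reach the markers.

Degenerate inputs: NaN intensities raise immediately; an all-zero window
fits to near-zero amplitude and area ≈ 0.

## Markers and decision rule

r₁₄₅₀ = A₁₄₅₀/A₁₀₀₃ and r₁₆₅₀ = A₁₆₅₀/A₁₀₀₃, requiring A₁₀₀₃ > 0
(violations raise a normalization error naming the subject). The ratios
are scale-invariant: multiplying a spectrum's intensities by c > 0
leaves both unchanged. A subject is positive on a marker iff the ratio
**strictly** exceeds the cutoff; an at-cutoff value is negative (the
decision rule is "greater than", and ties are resolved conservatively
toward non-disease). The two markers are reported separately; a joint
both-markers-positive accuracy appears in reports as clearly-labelled
supplementary output only.

## ROC, Youden, intervals

* **ROC** — thresholds are the distinct observed scores plus ±∞
  endpoints; sensitivity and 1 − specificity use the strict ">" rule.
  AUC by trapezoid, which on this construction equals the tie-corrected
  Mann–Whitney U/(n₊n₋) (property-tested against brute-force pair
  counting). Positive direction defaults to "greater" and is
  configurable.
* **AUC CI** — stratified bootstrap (positives and negatives resampled
  separately; 2.5/97.5 percentiles; default 2000 resamples, seeded,
  minimum 100), or DeLong's placement-value variance as the
  closed-form alternative. Intervals are clipped to [0, 1].
* **Youden cutoff** — exhaustive scan of observed thresholds maximizing
  J = sens + spec − 1; ties broken toward higher specificity, then lower
  cutoff. Reports carry both the raw observed threshold (used for all
  sens/spec/accuracy numbers) and a supplementary midpoint between it
  and the next lower observed score, a common reporting convention; note
  that applying the strict ">" rule at the midpoint would flip a subject
  sitting exactly at the raw threshold, so the raw threshold is
  authoritative.
* **Sensitivity/specificity CIs** — exact Clopper–Pearson from Beta
  quantiles: lower = B(α/2; s, n−s+1), upper = B(1−α/2; s+1, n−s), with
  endpoints 0 and 1 at s = 0 and s = n. Chosen because the exact method
  reproduces published operating-point interval arithmetic and has
  guaranteed ≥ nominal coverage.
* **KDE panels** — Gaussian kernels, Silverman bandwidth by default, on
  a grid padded three bandwidths beyond the sample range.

Report rounding: 3 decimals for proportions, 5 for AUC.

## Problem sizes used in checks

The default study is 48 subjects × 1401 grid points with three window
fits each (~3 s end to end). Statistical checks use: 200 random score
sets (n ≤ 30) for the pair-counting and threshold-scan oracles, 200
Monte-Carlo replicates for area recovery at SNR 20, 500 + 500 scores for
the binormal closed form, and 5000 binomial replicates (n = 25,
p = 0.9) for interval coverage.

## Known limitations

* Gaussian-only peak shapes; no Voigt/Lorentzian option.
* No baseline subtraction anywhere, by design; markers inherit a small
  class-independent area offset whenever a background is present.
* The component counts k per window are conventions, not estimates; no
  model selection (second-derivative counting, information criteria) is
  performed.
* Bootstrap AUC intervals at n = 48 are approximate; coverage can dip
  below nominal near AUC = 1 where the statistic saturates.
* Synthetic cutoff values live on the simulator's intensity scale and do
  not transfer to real instruments.
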