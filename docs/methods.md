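# Methods

## The measurement chain

An image enters as RGB(A); pixels with alpha < 128 are treated as removed
background and excluded from every denominator. Colors are reduced to
quantized RGB codes by mapping each channel to the nearest of L evenly
spaced values in {0, …, 255} (both endpoints included, halves rounding up).
L = 256 is the identity and is what the analysis scripts and acceptance run
use, since the synthetic renderer already paints from a small palette;
L = 6 is a reasonable default when ingesting camera JPEGs, emulating the
coarse palette reduction of GIF-style export. The exact reduction algorithm
of web image-analysis tools is undocumented, so uniform quantization is an
approximation, not a reproduction.

*Weed green* is defined by the strict rule G > R and G > B. Strictness
matters: decolorized soil is near-neutral (R = G = B) and must never count
as green, and all characteristic weed-green codes (e.g. 0-43-0, 51-85-51,
102-128-102, 153-170-102, 102-128-51, 51-85-0) pass strictly. From the
rule-passing codes, the top k (default 6) by pixel count summed over all
images are kept, optionally required to occur in every treatment group —
codes private to one group are more plausibly noise than weeds. Green cover
of an image (or of a zone image) is green pixels / unmasked pixels of that
image.

## Zone segmentation

Treated soil is bleached toward neutral gray; untreated soil is brown
(R > G > B). Per pixel, grayness = 1 − (max − min)/255 over the RGB
channels. Non-green pixels with grayness ≥ 0.85 and mean brightness in
[60, 220] seed the gray zone; other non-green pixels are nongray. A majority
vote over the (2r+1)² window (r = 3) removes speckle, with ties going to
nongray. Green pixels inherit the majority zone of non-green pixels in the
same window (nearest non-green pixel if the window has none), because a weed
physically stands on one zone's soil; excluding green pixels from zone areas
would instead distort each zone's denominator. The defaults separate the
synthetic gray codes (chroma 0) from the brown soil codes (chroma ≥ 55) with
a wide margin; on real images all three thresholds are configuration. The
procedure deliberately replaces an interactive, irreproducible
background-removal step with a deterministic one, so there is no ground
truth for *manual* masks to compare against — fidelity is assessed on
rendered fixtures with known disc geometry (recovered within 5% area error;
green pixel counts conserve exactly across zones by construction).

## The regression model

Observed green proportions y ∈ (0, 1) are modelled as
Beta(μφ, (1−μ)φ) — the standard mean/precision parameterization — with

    logit μ = α₀ + α₁P₀ + α₂P₁ + (β₀ + β₁P₀ + β₂P₁)·D
    log φ   = γ₀ + γ₁·D

D continuous in days, P₀/P₁ dummies for the nongray/gray zones, control as
reference. The day-dependent precision absorbs the visibly growing
pot-to-pot spread at later days. Exact 0/1 outcomes are compressed by
(y(n−1) + 0.5)/n before fitting. Two fits:

- **Maximum likelihood** (unconstrained): via the variable-dispersion beta
  regression in statsmodels (logit mean link, log precision link), started
  from logits of group×day cell means and a method-of-moments precision.
  Standard errors from the observed information.
- **Constrained Bayesian**: posterior ∝ likelihood × N(0, 2.5) priors on the
  six mean coefficients × N(0, 1) on γ₀, γ₁ × the hard indicator
  1{β₀ > 0, β₀+β₁ > 0, β₀+β₂ > 0} — weeds cannot un-grow, and the
  constraint also guarantees θ ratios below are well defined. Sampling is
  adaptive random-walk Metropolis: independent chains (per-chain substreams
  of one seed), proposal covariance initialized at (2.38²/d)·Σ̂_ML and
  refined during warmup from the accumulated sample covariance, with a
  global scale tuned toward 30% acceptance; the proposal is frozen after
  warmup. Split-R̂ and bulk ESS (via arviz, one chain per Metropolis chain)
  are attached to the output; R̂ > 1.05 warns rather than errors. Default
  budget: 4 chains × (1500 warmup + 3000 kept), which on the 48-row study
  design yields R̂ ≤ 1.03 and ESS in the hundreds within seconds.

For the pre-segmentation comparison the whole treated pot enters as a
single group "T" occupying the first dummy slot; coefficients of groups
absent from a fit are NaN so that accidentally predicting an unfitted group
fails loudly.

## Baseline adjustment and estimands

θ(d) = [μ(d) − μ(0)] / [1 − μ(0)] is the proportion of the initially
non-green area that is green by day d: it is 0 at d = 0 by construction,
equals μ(d) when the baseline vanishes, and for each group reduces to the
closed form (e^{a+bd} − e^{a})/(1 + e^{a+bd}) with that group's intercept a
and slope b (the identity is verified to 1e-12 in tests). Under the
constraints θ is strictly increasing in d and lies in [0, 1).

Estimands are the per-draw ratios θ_P1(5)/θ_C(5) and θ_P0(5)/θ_C(5) —
computed draw-by-draw and then summarized, the only order consistent with a
posterior interval on a ratio — reported as the posterior mean with an
equal-tailed 95% interval (linear-interpolation quantiles; an HDI is
available behind a flag). The unadjusted counterpart μ_T(5)/μ_C(5) from the
two-group ML fit is reported alongside to show the bias the adjustment and
segmentation remove. Growth curves are drawn both as pointwise posterior
means of θ(d) and as plug-in curves at the posterior-mean coefficients;
the two differ slightly because θ is nonlinear in the coefficients.

## The synthetic study

The generator is the package's test bed and defines its study conditions:
4 pots per group, photographs at days 1, 2, 4, 5; per-(pot, day) proportions
drawn from the beta model; 128×128 images painted from a small palette
(6 weed-green codes, brown soil codes, neutral gray codes) with an exact
pixel count of green, a central gray disc (radius 0.3 × image side) in
treated pots, and a background-noise floor implemented by recoloring a fixed
fraction (default 0.10) of non-weed pixels green — noise lives at the image
layer, matching its physical origin in lighting and processing, not in weed
biology. Seeding uses documented per-pot substreams
(SeedSequence spawn keys), so enlarging the design never perturbs existing
pots' draws.

Default truth: α₀ = −4.6 (essentially no true weed cover at day 0, on top
of which the 10% noise floor produces the apparent day-zero green), slopes
β₀ = 0.87, β₀+β₁ = 0.89, β₀+β₂ = 0.15 (control reaching ≈ 0.5 apparent
cover by day 5, nongray tracking control, gray-zone growth strongly
suppressed), log-precision 4.5 − 0.15·D (pot-to-pot SD of a few percentage
points, growing with the mean). These were fixed once to make the synthetic
study qualitatively resemble a real small bioassay with a sharply localized
treatment effect.

What the generator does *not* emulate: lighting gradients, shadows, camera
noise, leaf geometry (green pixels are scattered i.i.d.), irregular gray
zones, or block effects. Passing tests therefore demonstrate correctness of
the measurement and inference chain under the stated model, not robustness
to real-world photometric nuisance — the package's design leaves those to
the statistical adjustment, not the image processing.

## Numerical choices and edge cases

- logit⁻¹ is computed with `scipy.special.expit` (no overflow; saturates
  inside (0, 1)).
- Beta log-density via `gammaln`; proportions at exactly 0/1 raise a
  boundary error that names the nudge rule.
- φ must exceed 2 over the design days in the generator, keeping both beta
  shape parameters above their U-shaped-density regime.
- Segmentation tie-breaks: equal gray/nongray votes → nongray; an all-green
  image is a degenerate-segmentation error.
- Quantile definition: linear interpolation (numpy `method="linear"`),
  stated because interval endpoints at 12000 draws are sensitive to it in
  the third decimal.
- Problem sizes: the validation suite uses 320-observation recovery runs,
  50-replicate credible-interval calibration at the 4-pot design, and
  128×128 fixtures — sizes at which every check runs comfortably on a
  laptop while Monte-Carlo error stays well inside the asserted tolerances.

## Known limitations

- The chroma-threshold segmenter assumes gray vs brown soils; pots with
  very dark or washed-out soil need re-tuned thresholds.
- The model has no pot-level random effects: replicate pots are treated as
  independent given group and day, as in the two-fit analysis it mirrors.
- ML and Bayesian fits share the likelihood implementation's design
  matrices; the likelihood itself is cross-checked against an independent
  beta density in the tests.
- With only 4 pots per group the posterior for the precision submodel is
  prior-sensitive; the N(0,1) prior on γ₁ matters at this sample size.
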