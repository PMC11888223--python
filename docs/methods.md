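# Methods

This note documents the models implemented in `smallspot`, the choices
made where the design was genuinely open, and what the synthetic study
does and does not emulate.

## Scientific setting

The package links the local spectral topography of the trichromatic cone
mosaic to the visibility and color naming of small (2.25 arcmin, ~67 ms)
monochromatic increments at 543 and 680 nm delivered with adaptive-optics
retinal stabilization in the parafovea (2–2.5° temporal). Two quantities
organize everything:

- **proportion L** (p_L): the effective number of illuminated L cones over
  the effective illuminated L+M cones, computed by aperture-weighted
  integration of the retinal light distribution rather than by counting
  cone centres inside the nominal stimulus outline;
- **heterogeneity**: `1 − |p_L − 0.5| / 0.5`, equal to 1 when the local L:M
  ratio is 1 and 0 for a single-class neighbourhood.

## Optical forward model (`optics`)

The retinal light distribution is the unit-integral uniform square
convolved with a diffraction-limited point spread function for a 6.5 mm
pupil, aberrated by 0.05 D of residual defocus. The PSF comes from
scalar Fourier optics: a circular pupil with a quadratic wavefront whose
peak-to-valley optical path error is `D·r_pupil²/2` (D in diopters, r in
meters). Whether the residual defocus should be a Seidel (quadratic) or
Zernike-balanced term is not determined by the problem; the quadratic
convention is used and exposed. The convolution is done as a centred
circular FFT product so the distribution's centre is exactly at the grid
centre (a linear "same-mode" convolution is off by one pixel on even
grids, which biases mirror-symmetry tests).

Grid defaults: 0.11 arcmin/pixel (the instrument's sampling) on a
256-pixel grid for standalone PSFs, 192 for pipeline runs. A guard
raises when PSF energy reaches the outer two-pixel border (>0.1% of
total), the practical symptom of an under-sized grid; energy capture is
otherwise ≥99.9%. The stimulus is treated as monochromatic at its centre
wavelength for PSF purposes; the channel bandwidths matter only for the
photoreceptor excitation integrals.

Cone apertures are unit-volume Gaussians with FWHM 0.59 arcmin. The
per-class effective cone count is the integral of the light distribution
times the class's aperture sum. With unit-integral light these counts
are light shares (their ratios are what the analysis uses); the
`normalization="peak"` option rescales the light profile to unit peak so
the total reads as a stimulated-cone number (~4–5 cones for the default
mosaics, matching the scale expected for this stimulus and eccentricity).

The Monte Carlo site-selection null (8 equal-width bins × 10,000
iterations by default) uses a precomputed kernel — the light profile
smoothed by the aperture Gaussian — truncated where it falls below 1e-3
of its peak. Truncation changes p_L by <~1e-2 (far tails illuminate L
and M cones equally and cancel in the ratio) and makes the 10⁴-iteration
null run in seconds. Bins are left-closed/right-open with the last bin
closed. Random sites are drawn so the stimulus footprint stays inside
the classified patch.

## Synthetic mosaics (`mosaic`)

Jittered hexagonal lattices: parafoveal mosaics are near-hexagonal, and
the downstream analyses need only realistic local density plus a
controllable class composition. Classes are assigned i.i.d. (U, then S,
then L/M splits), with an optional `clumping` knob — rounds of
copy-your-neighbour reassignment — because real mosaics are patchy but
no clumping statistic is available to calibrate against. Cone spacing is
the mean edge length over *all* Delaunay edges; sliver triangles along a
patch boundary bias the mean slightly high (<5% on interior-dominated
patches of ~1000 cones), which tests account for. S-cone distances are
expressed in cone-spacing units.

## Photoreceptor model (`photoreceptors`)

Corneal quantal sensitivity per class:

    S(λ) = [1 − 10^(−d_eff · A(λ; λmax))] · 10^(−D_lens(λ) − D_mac(λ))

- **Absorbance template** A: the Govardovskii A1 nomogram (alpha + beta
  band), chosen because the RMSE scan varies λmax continuously, which
  rules out fixed tabulated fundamentals. Defaults: λmax M = 530.3 nm,
  S = 420.7 nm (field-standard values; the study itself constrains only
  the L-cone variants 555.5 / 558.9 / 563.4 nm, exposed as presets).
- **Axial density** d_eff = specific density × outer-segment length ×
  unbleached fraction. Specific density defaults to 0.015 /µm (a package
  default, not a measured value); outer-segment lengths 35.7 and 32.9 µm
  for the two default observers.
- **Bleaching**: steady-state unbleached fraction `k/(k + rate)` with
  half-bleach constant k = 10^6.4 isomerizations/s. The background
  (1702 cd·m⁻², 6.5 mm pupil) is converted to an isomerization rate as
  trolands × 10^2.1 — the scale on which the troland-domain cone
  half-bleach constant (10^4.3 Td) maps onto 10^6.4 isomerizations/s, so
  the chain is internally consistent by construction. This gives an
  unbleached fraction of ~0.26 for the default background.
- **Ocular media**: the lens template is a smooth exponential calibrated
  to the standard-observer density scale (~1.76 at 400 nm, ~0 in the deep
  red) with linear 2%/year age scaling about age 32; the macular template
  is a unit-peak Gaussian at 460 nm truncated beyond 550 nm, scaled by
  the peak MPOD. Peak MPOD between eccentricities e1 < e2 inverts the
  field-size-averaged density relation (`mpod_peak`), with the field-size
  function defaulting to `0.485·exp(−fs/6.132)`. These templates are
  deliberate parametric stand-ins for the published tabulations, which
  the configuration accepts as drop-in callables; at 543 and 680 nm both
  media are nearly transparent, so the detection analysis is insensitive
  to their exact shapes.
- **Primary excitations**: band-weighted mean sensitivity over a Gaussian
  spectrum whose half-width-at-half-maximum equals the quoted ±14.9 /
  ±13.5 nm channel bandwidths (the "±" is read as HWHM; an override
  exists). Integration is trapezoidal on an internal 0.015 nm grid.

## Additive detection model (`detection`)

At threshold the L+M mechanism's responses to the two primaries are
equal, giving

    S680/S543 = (p_L·L680 + w·(1−p_L)·M680) / (p_L·L543 + w·(1−p_L)·M543)

with per-quantum excitations from the observer's fundamentals and an
optional M weight w (default 1; 1.5 probes an M-dominant flicker-ERG
weighting). The curve is strictly increasing in p_L whenever
L680/L543 > M680/M543. The luminous-efficiency prediction is the
global-L-fraction-weighted sum of the L and M fundamentals (vertical
scale free). The RMSE-vs-λmax scan rebuilds the fundamentals at each
grid point (550–570 nm, 0.1 nm default) and scores predictions in the
linear ratio domain by default; the error domain is not pinned down by
the problem, so a log10 option is provided and the choice is logged.

## Psychophysics engine (`psychophysics`)

The simulated observer is a Weibull frequency-of-seeing function
p = γ + (1−γ−λ)(1−exp(−(I/α)^β)) with γ = 0, lapse λ = 0.02, slope β = 3
(typical for increment detection). QUEST+ runs on a 60-point log-spaced
intensity/threshold grid spanning 3 decades below the maximum intensity
and a 12-point slope grid (0.5–8); the posterior starts uniform and each
adaptive trial minimizes expected posterior entropy. Two staircases per
locus × wavelength (25 trials each) start at 25% and 75% of maximum and
are randomly interleaved with all other staircases in the block. On 20%
of trials the suggested intensity is replaced by a uniform draw on
[0, max]; these catch trials still update the posterior (they are valid
data at a known intensity) and enter the Weibull fit by default, with a
staircase-only mode available.

Threshold is the intensity at 50% overall seeing probability on the
maximum-likelihood Weibull fit (guess and lapse included). Fits with
all-seen or all-unseen data raise rather than extrapolate.

Delivery quality: trials are kept only if every frame's |x| and |y|
offsets are ≤0.75 arcmin. Simulated offsets are i.i.d. Gaussian with SD
0.09 / 0.10 arcmin (x / y) plus a heavy-tail contamination (one frame
thrown to 0.9–2.0 arcmin) whose per-subject rates, 12.4% and 16.4%, are
set so filtering reproduces the reported inclusion percentages. Per-trial
proportion L is recomputed at the locus centre plus the trial's mean
frame offset (a config switch reverts to the nominal centre).

## Color-naming analysis (`colornaming`, `glmm`)

A seen flash is an *expected* color response when called green at 543 nm
or red at 680 nm. Only seen trials enter the analyses (responses are
conditional on detection). Intensity enters as log2 of the multiple of
the local (fitted) threshold. Response matrices bin expected-response
rates over intensity × proportion-L cells, suppressing (not zeroing)
cells with fewer than 10 trials and flagging empty cells distinctly.
Tertile analysis splits per-trial heterogeneity at its empirical 1/3 and
2/3 quantiles (ties to the lower tertile) and reports per-bin rates,
counts, and median intensity.

The mixed model is

    logit(π) = β0 + β1·log2(intensity) + β2·heterogeneity
               + β3·(S-cone distance) + b_subject + b_wavelength

fit by maximum likelihood under the Laplace approximation: for each
candidate pair of random-intercept SDs, the joint (β, u) mode is found by
penalized IRLS, the Laplace-approximate marginal log-likelihood
`ℓ(β,u*) − ½u*ᵀD⁻¹u* − ½log det(I + D·ZᵀWZ)` is evaluated, and the two
variance parameters are optimized on the log scale. This is the standard
nAGQ = 1 scheme and yields a genuine likelihood, so nested models can be
compared by LR test (the heterogeneity term's contribution is tested
this way). Wald CIs for the fixed effects come from the β block of the
inverse joint Hessian, conditional on the variance estimates. A
displayed trial-level residual term has no role in a Bernoulli model and
is not implemented. With only two levels per grouping factor the
variance optimum can sit at the boundary; the fit then falls back to a
fixed-effects logistic regression (statsmodels GLM) with a warning. The
reported "adjusted R²" is the adjusted McFadden pseudo-R²,
`1 − (ℓ − k)/ℓ_null`; no numeric equivalence with other R² definitions is
claimed. Complete separation raises an error naming the offending
predictor.

## Synthetic study (`synthesize`)

Defaults emulate the two-observer study: global L/M ratios 1.47 and 3.66,
S fraction 5%, 2% unclassified cones, 32 and 26 loci, outer segments
35.7/32.9 µm, L λmax 563.4/558.9 nm, ages 40/27, eccentricities 2.0/2.5°,
spacings 1.1/1.25 arcmin (spacing at these eccentricities is not reported
for the observers; these are realistic parafoveal values giving ~4–5
effective cones per flash). Loci are picked quantile-spread over the
candidate p_L distribution, with a knob forcing majority-M loci (3 for
the L-rich observer). True 543 nm thresholds are lognormal about 0.002 of
maximum intensity (σ = 0.10 log10, so the 543 nm sensitivity IQR lands in
the observed 0.12–0.16 log10 range); true ratios are the additive-model
predictions times lognormal noise (σ = 0.10 log10, placing the 680 nm
IQR near the observed 0.22–0.34 once the topography signal is added).
Color responses are single Bernoulli draws from the logistic model with
β1 = ln 2.94, β2 = ln 5.51, β3 = 0, random-intercept SDs 0.3 (subject)
and 1.0 (wavelength), plus a 1% non-expected color rate to exercise those
paths. Every stochastic stage gets a sub-seed derived from the master
seed; identical configurations reproduce the output tree byte for byte.

**What the generator does not emulate:** real mosaics' spatial clumping
statistics (the knob exists but is off by default), cone classification
errors, session effects and observer learning, opponent-channel
contributions to detection (the generator *is* the additive model plus
noise, so the synthetic data cannot show the systematic underprediction
a real opponent contribution would produce), and intensity-dependent
response-time structure. Passing tests therefore demonstrate that the
pipeline recovers what the stated models generate — not that those models
exhaust real small-spot data.

## Numerical choices and problem sizes

Simulations in the test suite and analysis scripts use the study-scale
defaults (58 loci, 2×25-trial staircases, 10,000 Monte Carlo iterations
in the analysis drivers; smaller counts only where a unit test needs a
toy case). GLMM recovery checks use n = 5,000 trials × 100 replicates
for CI coverage and 200 scaled-down replicates (n = 600) for the LR
type-I rate. Histogram and tertile bins are left-closed/right-open with
the last bin closed. Optimizers: Nelder-Mead for the Weibull (two
starts) and the GLMM variance profile; penalized IRLS with step damping
for the joint mode. Degenerate inputs (all-seen staircases, mosaics
without S cones, empty trial tables, non-nested model comparisons) raise
typed exceptions rather than returning sentinel values.

## Known limitations

- The lens/macular stand-ins are accurate to the published templates
  only at the ~0.05 OD level in the blue; analyses at short wavelengths
  would need the tabulated templates injected via config.
- The Laplace likelihood with two-level grouping factors estimates
  variance components noisily (a known property, mitigated by the
  fixed-effects consistency check and fallback).
- The fast sampling kernel trades ~0.01 absolute accuracy in p_L for
  speed; exact per-locus values use the full-grid path.
- Weibull slope is fixed across loci in the generator; real slopes vary.
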