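# smallspot

Local variations in the L/M cone ratio shape how small, brief flashes of
long- and middle-wavelength light are detected and named. `smallspot` is
an analysis pipeline for adaptive-optics small-spot psychophysics that
links the two: it models the retinal light distribution of a stabilized
2.25-arcmin stimulus, samples it through the cone mosaic to get the local
proportion of L cones, predicts 680/543 nm sensitivity ratios with an
additive L+M detection model, simulates QUEST+ staircase sessions, and
fits a mixed-effects logistic model of color naming. It is written for
visual psychophysicists and retinal modellers who want each of those
stages as a tested, reusable library — exercised end to end on synthetic
cone mosaics and simulated observers, since per-cone classified human
data are not publicly available.

## Core models

**Proportion L.** The stimulus light distribution is the unit-integral
square convolved with a diffraction-limited PSF (6.5 mm pupil, 0.05 D
residual defocus). Each cone contributes a unit-volume Gaussian aperture
(FWHM 0.59 arcmin); the effective count of class *c* is
∫ light(x,y) · Σᵢ aperture (x,y) dx dy over cones of that class, and
p_L = count_L / (count_L + count_M). Local heterogeneity is
1 − |p_L − 0.5| / 0.5.

**Additive detection model.** With per-quantum cone excitations L₆₈₀,
M₆₈₀, L₅₄₃, M₅₄₃ from observer-specific fundamentals (Govardovskii
nomogram, lens/macular filtering, axial density with steady-state
bleaching), the predicted sensitivity ratio at a locus is

    S₆₈₀ / S₅₄₃ = (p_L·L₆₈₀ + w(1−p_L)·M₆₈₀) / (p_L·L₅₄₃ + w(1−p_L)·M₅₄₃)

with unit M weight by default (w = 1.5 reproduces a flicker-ERG-motivated
variant). Scanning the L-cone λmax and scoring the RMSE against fitted
ratios locates each observer's best pigment variant.

**Color naming.** For seen trials, the probability of the "expected"
response (green at 543 nm, red at 680 nm) follows

    logit(π) = β₀ + β₁·log₂(intensity) + β₂·heterogeneity
               + β₃·(S-cone distance) + b_subject + b_wavelength

fit by Laplace maximum likelihood (random intercepts for subject and
wavelength), with a likelihood-ratio test of the heterogeneity term.

See `docs/methods.md` for assumptions, parameter defaults, and knowing
what the synthetic study does and does not emulate.

## Worked example

Run the numbered analysis scripts in order (they share `results/`):

```bash
python analysis/01_synthesize_study.py --seed 0
python analysis/02_mosaic_sampling.py
python analysis/03_fit_thresholds.py
python analysis/04_detection_model.py
python analysis/05_color_naming.py
```

`01` builds two synthetic observers (global L/M ratios 1.47 and 3.66, 32
and 26 test loci) and simulates 5,800 staircase trials. `03` applies the
≤0.75 arcmin delivery filter and fits Weibull thresholds:

```
S1: 86.97% of trials passed the delivery filter; 32 loci fit; median 543-680
    sensitivity difference 1.55 log10; IQR 543 0.12, 680 0.23 log10
S2: 83.27% of trials passed the delivery filter; 26 loci fit; median 543-680
    sensitivity difference 1.69 log10; IQR 543 0.17, 680 0.24 log10
```

The 680 nm sensitivities spread about twice as widely as the 543 nm ones
— the signature of local L/M topography, since L and M cones are nearly
equally sensitive at 543 nm. `04` quantifies that link and scans the
additive model over L-cone λmax:

```
S1: ratio vs proportion L Spearman rho = 0.78 (p = 1.5e-07, n = 32)
    RMSE minimum at lambda_max = 565.7 nm
    1.5x M-weight variant changes best-fit RMSE by +11.2%
S2: ratio vs proportion L Spearman rho = 0.67 (p = 0.00019, n = 26)
    RMSE minimum at lambda_max = 558.6 nm
```

The fitted ratios rise with proportion L, and the RMSE minima separate
the two observers' L pigments (the generator used 563.4 vs 558.9 nm).
`05` fits the color-naming model to the 3,154 seen trials:

```
    log2_intensity: odds factor 2.98 (95% CI [2.73, 3.24])
    heterogeneity: odds factor 3.47 (95% CI [2.02, 5.94])
    s_cone_distance: odds factor 1.11 (95% CI [0.98, 1.26])
    LR test of heterogeneity: stat 19.08, delta df 1, delta AIC -17.08, p = 1.3e-05
```

Doubling intensity triples the odds of a chromatic report; moving from a
single-class neighbourhood to a balanced one raises them several-fold
(the generating odds factors were 2.94 and 5.51); S-cone proximity has no
effect (generating odds factor 1). The same pipeline is available as a
console tool (`smallspot report --seed 0 --outdir results`) driven by a
YAML run configuration.

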