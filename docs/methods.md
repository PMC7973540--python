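# Methods

## Data model and processing chain

A hyperspectral acquisition is an H × W × λ cube of 16-bit counts, one
narrow-band (10 nm FWHM) image per 1 nm step from 320 to 680 nm
(361 bands). Processing is strictly staged:

1. **Instrument correction** divides every band by the product of the
   pellicle beam-splitter transmittance and the relative light input at
   that wavelength. Dividing by the *product* (rather than applying the
   factors sequentially in mixed order) is the only reading under which
   simulating the instrument and correcting for it compose to the
   identity, which the suite verifies to < 1e-3 relative error on the
   float path.
2. **Registration** aligns each band to a reference band by pure
   translation, estimated with phase cross-correlation. The reference
   defaults to the brightest band (maximal mean intensity, ≈ 480 nm in
   retina-like scenes). Integer mode recovers clean integer shifts
   exactly; subpixel refinement is available but off by default. Pixels
   that enter from outside the field after a shift become NaN — invalid,
   not zero — so downstream means are unbiased. Constant bands cannot be
   registered and are flagged degenerate with a zero shift.
3. **Masking** stores the *keep* set (1 = analyse): excluded
   vessel/optic-disc pixels become NaN in every band. Manually drawn masks
   are the first-class input; `auto_vessel_mask` is a convenience that
   thresholds the ~560 nm band (the hemoglobin isosbestic point, where
   arteries and veins are equally dark) at 0.75 × median, removes the
   brightest blob as the disc, and dilates by 2 px. Its thresholds are
   relative, so the mask is invariant to global intensity scaling.
   Masking operates on corrected (float) cubes only, because invalid
   pixels are NaN-encoded and raw cubes must stay integer.
4. **Quantification.** Profiles (per-band means over an ROI or the whole
   keep-set) are baseline-corrected at λ_base = 380 nm and normalized at
   λ_ref = 670 nm; the same formula evaluated per pixel at
   λ_Aβ = 475 nm yields the spectral Δ map. Named wavelengths are
   resolved to the nearest band within ±1 nm, so decimated grids must
   still contain the anchors (the bundled 5 nm grid does). Pixels whose
   denominator magnitude falls below 1e-9 × the cube dynamic range are
   flagged invalid rather than allowed to blow up. Whole-image profiles
   are averaged first and normalized second; the Δ map path is per-pixel.
   Both orders are exposed because averaging and this normalization do
   not commute.
5. **Residuals.** Group residual = mean(amyloid) − mean(control) per band,
   with 95% confidence half-widths of the *control* group only
   (t-distribution, n−1 df) for display. Band normalization divides a
   residual by its mean over the closed 450–475 nm band (making that mean
   exactly 1), which puts ages and preparations on a common
   short-wavelength scale; it is scale-invariant and idempotent. The
   alternate normalization divides a profile by its mean over all bands —
   shape-preserving, mean exactly 1.

## Statistics

- **Normality:** one-sample KS against a normal with the sample moments.
  Because the null parameters are estimated from the same data, the plain
  KS p-value is conservative; a `method="lilliefors"` option (statsmodels)
  gives a calibrated test. The suite checks calibration properties rather
  than a fixed rejection rate, since even Lilliefors rejects uniform
  samples at n = 200 only ~70% of the time at p < 0.01.
- **Outliers:** two-sided Grubbs test with the standard t-based critical
  value. Subject screening is at the profile level (each subject's mean
  normalized value within its group, one pass): removing whole subjects
  rather than single wavelength points preserves the repeated-measures
  structure.
- **ANOVA:** mixed design — group between subjects, wavelength within.
  Sums of squares and F come from `pingouin.mixed_anova` (which handles
  the unequal group sizes of the cohort design); the Greenhouse–Geisser
  epsilon is computed here from the **pooled within-group covariance** of
  the repeated measures (group means centred out) and applied to both
  within-subject effects (wavelength and interaction). pingouin itself
  corrects only the within main effect and pools across groups without
  centring; the pooled estimator is the textbook choice for mixed
  designs. ε is clipped to [1/(k−1), 1], and corrected p-values are never
  smaller than uncorrected ones. An independent brute-force
  sums-of-squares oracle validates the F statistics to 1e-8 on random
  balanced designs.
- **FDR:** the adaptive two-stage linear step-up procedure
  (Benjamini–Krieger–Yekutieli 2006, Definition 6): stage 1 runs the
  linear step-up at α′ = α/(1+α), the null count is estimated as
  m₀ = m − r₁, and stage 2 re-runs the step-up at α′·m/m₀. Reported
  q-values are scaled so that "significant" is exactly q ≤ α; they match
  statsmodels' `fdrcorrection_twostage(method="bky")` to rounding. The
  adaptive procedure's discovery set contains the plain BH set in
  practice, but not as a theorem — a p-value sitting between α/(1+α) and
  α on a single test is rejected by BH and not by the two-stage
  procedure; the property test therefore uses seeded random p-lists.
- **Post hoc:** unpaired equal-variance t-test per wavelength (the
  genotype contrast at each band), FDR-corrected across bands.
  At the normalization anchors (380, 670 nm) both groups are constant by
  construction; those zero-variance, zero-difference bands get p = 1.

## The phantom generator

The generator emulates the statistical and optical structure the analysis
assumes — not a radiometric eye model. Background tissue reflectance is

    R(λ) = bg · L(λ) · [1 + a_o (450/λ)⁴ + a_p exp(−(λ−c)²/(2w²))]

with `bg` the reflectance as a fraction of the 16-bit full scale
(default 0.30), `L(λ)` a sigmoidal lens/ocular-media transmission
(center 420 nm, width 25 nm, depth set by `lens_yellowing`, → 1 in the
red), a Rayleigh-like oligomer term normalized at 450 nm (amplitude
`a_o`), and a Gaussian plaque hump (amplitude `a_p`, center 550 nm,
width 40 nm). Rayleigh λ⁻⁴ is the minimal physically motivated form for
scatter by particles well below the wavelength; the 550 nm Gaussian
encodes the observed age-emergent mid-wavelength peak without claiming a
mechanism. With lens yellowing 0.8 this yields mean Δ(475) ≈ 0.91 for the
wild-type preset and ≈ 1.43 for the young-transgenic preset, and Δ is
provably strictly increasing in `a_o` (numerator and denominator of Δ are
linear in `a_o` with positive and negative slope respectively over the
usable range).

Vessels radiate from the optic disc and attenuate the tissue spectrum by
exp(−thickness · μ(λ, s)), where μ is a smooth hemoglobin-like stand-in:
a saturation-independent base plus (1−s) · 0.5 · tanh((λ−560)/50). The
odd term vanishes at 560 nm (exact isosbestic) and makes
high-saturation arteries brighter than veins above 600 nm. The disc is a
bright (×1.6) blob; vessel masks never overlap it. These spectral shapes
are test fixtures pinned to qualitative anchors, not literature extinction
curves. A 10 nm-FWHM Gaussian smoothing along wavelength simulates the
optical bandwidth (the exact isosbestic equality then holds to ~1e-3;
switch `simulate_bandwidth` off for exactness). Acquisition adds a smooth
multiplicative vignette (which cancels exactly in Δ), optional integer
per-band jitter (cyclic, recorded as ground truth), Gaussian read noise
(default 200 counts ≈ 1% of signal, independent across bands), clipping
and 16-bit quantization; configurations that would silently saturate more
than 1% of noiseless pixels are rejected. Everything is deterministic
given the seed.

Droplet phantoms reuse the same spectral model inside a circular droplet.
The amyloid-solution preset combines λ⁻⁴ scatter (a_o = 0.35) with a
near-UV attenuation (the lens sigmoid at depth 0.5, standing in for the
solution's short-wavelength cutoff) — without that cutoff a λ⁻⁴ medium
would be brighter at 380 nm than at 670 nm and the baseline/reference
normalization would invert, which the measured droplet profiles clearly
do not do. Visible specks are modelled as large aggregates in the Mie
regime: a near-neutral ("white") ×1.6 brightness factor plus a mild extra
Rayleigh term, so with-speck ROIs exceed speck-free ROIs at 475 nm while
both carry the soluble-scatter signature. The PBS vehicle preset is flat
to within <5% across 380–680 nm.

Presets (`wt`, `tg-young`, `tg-mid`, `tg-old`) encode the age
progression: strong oligomer scatter and no plaque hump when young
(a_o = 0.50), a growing plaque hump with reduced oligomer term when aged
(a_o = 0.30, a_p = 0.30), mirroring the histological pattern of oligomers
peaking early and plaques accumulating late. The aged residual
consequently shows a local maximum near 545 nm that the young preset
lacks.

## Simulated study conditions

The reproduction pipelines use the study's sample sizes: droplets — two
amyloid and two vehicle droplets, 5 with-speck + 5 speck-free ROIs per
amyloid droplet and 5 ROIs per vehicle droplet (10/10/10); retinae —
three cohorts of transgenic vs wild-type at n = 9/12, 9/13 and 8/15.
Subjects vary biologically: scatter amplitudes are truncated-normal
around the preset (CV ≈ 15% plus a small floor), background reflectance
N(0.30, 0.02), lens yellowing N(preset, 0.04). Cubes are 64 × 64 pixels
on a 5 nm-step grid (73 bands, containing all anchor wavelengths); the
pipeline mathematics is grid-agnostic and runs unchanged on the full
361-band grid. The phantom's ground-truth keep-mask stands in for the
human annotator (shifted by the registration reference band's jitter,
as an annotator would draw on the registered stack). Null-calibration
simulations use 32 × 32 cubes without jitter.

What passing tests show — and what they do not: the phantoms share the
pipeline's parametric families, so parameter-recovery and progression
tests validate the *software chain* (formulas, normalization order,
invalid-pixel handling, error control), not the biological claim. Real
retinae add focus and illumination drift, eye movement beyond pure
translation, RNFL birefringence and media opacities that the generator
deliberately omits.

## Numerical choices and limitations

- Named-wavelength lookup tolerance ±1 nm; Δ denominator invalid below
  1e-9 × dynamic range; normalization with coincident anchor intensities
  raises rather than returning infinities.
- Registration of already-registered stacks estimates on median-filled
  NaN fields and returns zero shifts (idempotence).
- Instrument profiles may be tabulated coarsely and are linearly
  interpolated onto the working grid (recorded in provenance); whether
  the original manufacturer curve was sampled natively at 1 nm is
  unknowable, so interpolation is configurable behaviour, not an
  assertion.
- Vessel oxygenation is exposed (`artery_saturation`, `vein_saturation`)
  but no realism claim is attached above 600 nm, where normalization and
  oxygenation effects cannot be separated.
- The CLI (`retinaspec …`) is a thin layer; all behaviour lives in the
  library and is tested there.
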