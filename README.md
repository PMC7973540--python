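# retinaspec

Quantification of hyperspectral retinal reflectance, built around the
light-scatter signature of amyloid-beta (Aβ). Soluble Aβ oligomers and
insoluble plaques — the protein hallmarks of Alzheimer's disease — scatter
short-wavelength visible light, and that excess reflectance is measurable
in the living retina with a hyperspectral ophthalmoscope: one narrow-band
image per wavelength, 320–680 nm in 1 nm steps (361 wavebands), stacked
into an H × W × λ cube. `retinaspec` implements the full analysis chain
for such cubes, together with a synthetic optical phantom generator so the
pipeline can be exercised, validated and benchmarked without animal data.

It is aimed at researchers working on retinal spectroscopy / oximetry-style
image analysis who need a tested, scriptable reference implementation of
this quantification.

## The quantification

Raw counts are first corrected for the instrument's spectral throughput
(pellicle beam splitter and light source):

    I_corr(λ) = I_raw(λ) / (T_pellicle(λ) · L_input(λ))

Bands are aligned by pure-translation registration (phase
cross-correlation), major vessels and the optic disc are masked out, and
spectra are baseline-corrected and normalized:

    norm(λ) = (I(λ) − I(λ_base)) / (I(λ_ref) − I(λ_base)),
    λ_base = 380 nm,  λ_ref = 670 nm

Evaluated per pixel at the amyloid criterion wavelength λ_Aβ = 475 nm this
is the **spectral Δ map**,

    Δ = (I_475 − I_380) / (I_670 − I_380),

which sits near 1 in control tissue and rises toward ~1.5 where
short-wavelength scatter is present; rendered on a fixed color scale it
gives the topographic heat maps. Group contrasts are summarized as
per-wavelength **residuals** (amyloid mean − control mean of normalized
spectra), optionally normalized to their 450–475 nm band mean, and tested
with a mixed-design repeated-measures two-way ANOVA (Greenhouse–Geisser
corrected) plus per-wavelength t-tests under the adaptive two-stage linear
step-up FDR procedure (Benjamini–Krieger–Yekutieli), α = 0.05.

The phantom generator produces 16-bit retina-like cubes (lens yellowing,
Rayleigh-like λ⁻⁴ oligomer scatter, a Gaussian ~550 nm plaque hump,
vessels with a 560 nm artery/vein isosbestic point, optic disc, noise,
band jitter) and droplet-like cubes with visible aggregate specks — each
with ground-truth masks and noiseless references.

## Worked example

```python
import retinaspec as rs

params = rs.preset_params("tg-young", seed=1)     # transgenic-like phantom
cube, truth = rs.generate_phantom_retina(params)  # 16-bit raw cube + truth
instr = rs.make_default_instrument_profile(params.grid)
raw = rs.apply_instrument(cube, instr)            # what the camera records
corr = rs.correct_intensity(raw, instr)
reg = rs.register_translation(corr)
masked = rs.apply_mask(reg.registered, rs.ExclusionMask(truth.keep_mask))
dmap = rs.compute_delta_map(masked)               # per-pixel spectral Delta
print(f"mean spectral Delta(475) = {dmap.mean():.3f}")
rs.delta_heatmap(dmap, "tg_young.png")
```

This prints `mean spectral Delta(475) = 1.432` — i.e. the transgenic-like
phantom sits near 1.5 on the Δ scale, versus ≈ 0.91 for the `"wt"` preset:
the short-wavelength scatter raises 475 nm reflectance relative to the
670 nm reference. The same flow is available from the shell:

```sh
retinaspec simulate retina --preset tg-young --seed 1 --out sim/
retinaspec exposure --irradiance 708.8 --pupil-mm 2.3   # -> 29.4 uW
retinaspec reproduce-invivo --seed 1 --out invivo_report/
```

`reproduce-invivo` simulates three age cohorts (transgenic n = 9, 9, 8 vs
wild-type n = 12, 13, 15), runs the full chain per subject and writes
residual tables, ANOVA/post-hoc CSVs, heat maps and a manifest;
`reproduce-invitro` does the droplet experiment (10 with-speck, 10
speck-free, 10 vehicle ROIs).

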