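"""Synthetic optical phantoms with known ground truth.

The generator emulates the statistical and optical structure that the
analysis pipeline assumes, at desk scale:

* retina-like cubes — a smooth ocular-media (lens) transmission that
  attenuates short wavelengths, an amyloid scatter signature made of a
  Rayleigh-like (lambda^-4) oligomer term plus a Gaussian plaque hump near
  550 nm, dark vessels whose artery/vein contrast vanishes at the 560 nm
  isosbestic point and reverses above 600 nm, a bright optic disc, smooth
  vignetting, optional per-band translation jitter, and Gaussian read noise
  quantized to 16-bit counts;
* droplet-like cubes — a suspended-droplet region carrying the same
  spectral model with bright localized aggregate specks.

The hemoglobin-like and lens curves are smooth parametric stand-ins pinned
to qualitative anchors (isosbestic at 560 nm, arteries brighter than veins
above 600 nm, short-wavelength lens attenuation); they are test fixtures,
not radiometric claims.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .core_io import InstrumentProfile, SpectralCube, WavelengthGrid

__all__ = [
    "PhantomParams", "PhantomTruth", "PRESETS", "preset_params",
    "tissue_reflectance_model", "generate_phantom_retina",
    "generate_droplet_image", "apply_instrument",
    "make_default_instrument_profile",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class PhantomParams:
    """Generative parameters for one phantom acquisition.

    Amplitudes are dimensionless multipliers of the background reflectance;
    ``background_level`` is the mean tissue reflectance as a fraction of the
    16-bit full scale; ``noise_sd`` is additive Gaussian noise in counts.
    """

    height: int = 64
    width: int = 64
    grid: WavelengthGrid = field(default_factory=lambda: WavelengthGrid.decimated(5.0))
    background_level: float = 0.30
    oligomer_scatter_amp: float = 0.04
    plaque_scatter_amp: float = 0.0
    plaque_center_nm: float = 550.0
    plaque_width_nm: float = 40.0
    lens_yellowing: float = 0.8
    vessel_count: int = 5
    vessel_width_px: int = 5
    artery_fraction: float = 0.4
    optic_disc_radius_px: int = 8
    noise_sd: float = 200.0
    seed: int = 0
    # secondary optics / acquisition knobs
    artery_saturation: float = 0.97
    vein_saturation: float = 0.55
    vessel_thickness: float = 1.2
    disc_brightness: float = 1.6
    vignette_strength: float = 0.15
    simulate_bandwidth: bool = True
    jitter_px: int = 0
    full_scale: int = 65535
    # droplet specks: large aggregates scatter near-neutrally ("white"),
    # so a broadband brightness factor plus a mild extra Rayleigh term
    speck_brightness: float = 1.6
    speck_scatter_boost: float = 0.15

    def __post_init__(self) -> None:
        if min(self.oligomer_scatter_amp, self.plaque_scatter_amp,
               self.lens_yellowing, self.noise_sd) < 0:
            raise ValueError("amplitudes, yellowing and noise_sd must be >= 0")
        if self.height < 1 or self.width < 1:
            raise ValueError("image dimensions must be positive")
        if not 0 <= self.artery_fraction <= 1:
            raise ValueError("artery_fraction must lie in [0, 1]")
        if not 0 < self.background_level:
            raise ValueError("background_level must be positive")
        r = self.optic_disc_radius_px
        if 2 * r >= min(self.height, self.width):
            raise ValueError("optic disc does not fit in the image")
        if self.vessel_width_px < 1 and self.vessel_count > 0:
            raise ValueError("vessel width must be >= 1 px")


@dataclass
class PhantomTruth:
    """Ground truth for a generated phantom (for validation only)."""

    vessel_mask: np.ndarray
    disc_mask: np.ndarray
    noiseless_cube: SpectralCube
    params: PhantomParams
    artery_mask: np.ndarray | None = None
    vein_mask: np.ndarray | None = None
    band_shifts: np.ndarray | None = None  # (L, 2) injected (dy, dx) per band
    speck_centers: list[tuple[int, int]] = field(default_factory=list)

    @property
    def keep_mask(self) -> np.ndarray:
        """The analysis keep-mask: everything but vessels and disc."""
        return ~(self.vessel_mask | self.disc_mask)


# ------------------------------------------------------------ spectral model

def _lens_transmission(lam: np.ndarray, yellowing: float) -> np.ndarray:
    """Ocular-media transmission: short wavelengths attenuated, -> 1 in the
    red; ``yellowing`` in [0, 1] scales the attenuation depth."""
    s = 1.0 / (1.0 + np.exp(-(np.asarray(lam, float) - 420.0) / 25.0))
    return (1.0 - yellowing) + yellowing * s


def _scatter_factor(params: PhantomParams, lam: np.ndarray) -> np.ndarray:
    """1 + oligomer (Rayleigh-like, normalized at 450 nm) + plaque hump."""
    lam = np.asarray(lam, dtype=float)
    oligo = params.oligomer_scatter_amp * (450.0 / lam) ** 4
    plaque = params.plaque_scatter_amp * np.exp(
        -0.5 * ((lam - params.plaque_center_nm) / params.plaque_width_nm) ** 2)
    return 1.0 + oligo + plaque


def tissue_reflectance_model(params: PhantomParams, lam) -> np.ndarray | float:
    """Background tissue reflectance R(lambda), as a fraction of full scale.

    R = background_level * L(lambda) * [1 + a_o (450/lambda)^4
        + a_p exp(-(lambda - center)^2 / (2 width^2))]

    where L is the lens transmission (monotone non-decreasing, -> 1 at long
    wavelengths). ``lam`` may be a scalar or array; it must lie within the
    phantom's wavelength grid range.
    """
    lam_arr = np.atleast_1d(np.asarray(lam, dtype=float))
    wl = params.grid.wavelengths_nm
    if lam_arr.min() < wl[0] - 1e-9 or lam_arr.max() > wl[-1] + 1e-9:
        raise ValueError("wavelength outside the phantom grid range")
    r = (params.background_level
         * _lens_transmission(lam_arr, params.lens_yellowing)
         * _scatter_factor(params, lam_arr))
    return r if np.ndim(lam) else float(r[0])


def _hemoglobin_mu(lam: np.ndarray, saturation: float) -> np.ndarray:
    """Hemoglobin-like absorption coefficient (arbitrary units).

    A smooth stand-in with the two anchors the vessel contrast needs:
    identical for all saturations at 560 nm, and lower for high saturation
    (arteries) above 600 nm so arteries render brighter than veins there.
    """
    lam = np.asarray(lam, dtype=float)
    base = (2.5 * np.exp(-(((lam - 420.0) / 60.0) ** 2))
            + 1.1 * np.exp(-(((lam - 555.0) / 45.0) ** 2))
            + 0.10)
    delta = 0.5 * np.tanh((lam - 560.0) / 50.0)
    return np.maximum(base + (1.0 - saturation) * delta, 0.02)


def _vessel_transmittance(params: PhantomParams, lam: np.ndarray,
                          saturation: float) -> np.ndarray:
    mu = _hemoglobin_mu(lam, saturation)
    return np.exp(-params.vessel_thickness * mu)


def _smooth_spectrum(values: np.ndarray, grid: WavelengthGrid) -> np.ndarray:
    """Simulate the finite optical bandwidth by Gaussian smoothing along
    wavelength with FWHM = grid.bandwidth_nm."""
    step = float(np.median(np.diff(grid.wavelengths_nm)))
    sigma = grid.bandwidth_nm * _FWHM_TO_SIGMA / step
    return gaussian_filter1d(values, sigma, mode="nearest")


def _class_spectra(params: PhantomParams) -> dict[str, np.ndarray]:
    """Noiseless per-class spectra in counts (tissue, artery, vein, disc)."""
    lam = params.grid.wavelengths_nm
    tissue = params.full_scale * np.asarray(
        tissue_reflectance_model(params, lam))
    spectra = {
        "tissue": tissue,
        "artery": tissue * _vessel_transmittance(
            params, lam, params.artery_saturation),
        "vein": tissue * _vessel_transmittance(
            params, lam, params.vein_saturation),
        "disc": tissue * params.disc_brightness,
    }
    if params.simulate_bandwidth:
        spectra = {k: _smooth_spectrum(v, params.grid)
                   for k, v in spectra.items()}
    return spectra


# -------------------------------------------------------------- scene layout

def _vignette(params: PhantomParams) -> np.ndarray:
    yy, xx = np.mgrid[0:params.height, 0:params.width]
    cy, cx = (params.height - 1) / 2.0, (params.width - 1) / 2.0
    r2 = ((yy - cy) ** 2 + (xx - cx) ** 2)
    r2max = max(cy, cx) ** 2 + 1e-12
    return 1.0 - params.vignette_strength * r2 / r2max


def _disc_center(params: PhantomParams) -> tuple[float, float]:
    # slightly off-center, as the optic nerve head sits nasally
    return (params.height * 0.5, params.width * 0.38)


def _layout_masks(params: PhantomParams, rng: np.random.Generator
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disc, artery and vein masks. Vessels radiate from the disc center;
    vessel masks never overlap the disc mask."""
    h, w = params.height, params.width
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = _disc_center(params)
    disc = ((yy - cy) ** 2 + (xx - cx) ** 2
            <= params.optic_disc_radius_px ** 2)
    if params.optic_disc_radius_px <= 0:
        disc = np.zeros((h, w), dtype=bool)

    artery = np.zeros((h, w), dtype=bool)
    vein = np.zeros((h, w), dtype=bool)
    n_art = int(round(params.artery_fraction * params.vessel_count))
    angles = rng.uniform(0.0, 2.0 * np.pi, size=params.vessel_count)
    # spread angles to avoid near-duplicate rays
    angles = np.sort(angles) + np.linspace(
        0, 2 * np.pi, params.vessel_count, endpoint=False)
    half = params.vessel_width_px / 2.0
    for i, th in enumerate(angles):
        ux, uy = np.cos(th), np.sin(th)
        # signed distance of each pixel to the ray from (cy, cx) along (uy, ux)
        dy, dx = yy - cy, xx - cx
        along = dy * uy + dx * ux
        perp = np.abs(dy * ux - dx * uy)
        band = (perp <= half) & (along >= 0)
        band &= ~disc
        if i < n_art:
            artery |= band
        else:
            vein |= band
    vein &= ~artery
    return disc, artery, vein


def _paint_scene(params: PhantomParams, disc: np.ndarray, artery: np.ndarray,
                 vein: np.ndarray) -> np.ndarray:
    """Compose the noiseless H x W x L scene in counts."""
    spectra = _class_spectra(params)
    h, w = params.height, params.width
    nl = len(params.grid)
    scene = np.empty((h, w, nl), dtype=np.float64)
    scene[:] = spectra["tissue"]
    scene[artery] = spectra["artery"]
    scene[vein] = spectra["vein"]
    scene[disc] = spectra["disc"]
    scene *= _vignette(params)[:, :, None]
    return scene


def _check_saturation(scene: np.ndarray, params: PhantomParams) -> None:
    frac = float(np.mean(scene > params.full_scale))
    if frac > 0.01:
        raise ValueError(
            f"{100 * frac:.1f}% of noiseless pixels exceed the {params.full_scale}"
            " count full scale; lower background_level or disc_brightness")


def _acquire(scene: np.ndarray, params: PhantomParams,
             rng: np.random.Generator
             ) -> tuple[np.ndarray, np.ndarray]:
    """Jitter per band (cyclic shifts), add noise, clip and quantize."""
    _check_saturation(scene, params)
    nl = scene.shape[2]
    shifts = np.zeros((nl, 2), dtype=int)
    data = scene
    if params.jitter_px > 0:
        data = scene.copy()
        shifts = rng.integers(-params.jitter_px, params.jitter_px + 1,
                              size=(nl, 2))
        for b in range(nl):
            data[:, :, b] = np.roll(data[:, :, b],
                                    (shifts[b, 0], shifts[b, 1]), axis=(0, 1))
    if params.noise_sd > 0:
        data = data + rng.normal(0.0, params.noise_sd, size=data.shape)
    data = np.clip(np.rint(data), 0, params.full_scale).astype(np.uint16)
    return data, shifts


# ----------------------------------------------------------------- retinae

def generate_phantom_retina(params: PhantomParams
                            ) -> tuple[SpectralCube, PhantomTruth]:
    """Generate one retina-like acquisition.

    Returns the quantized 16-bit cube (stage ``raw`` in scene units, i.e.
    as if already instrument-corrected; push it through
    :func:`apply_instrument` to simulate the camera) and the ground truth
    (noiseless cube, vessel/disc masks, injected band shifts).
    Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    disc, artery, vein = _layout_masks(params, rng)
    scene = _paint_scene(params, disc, artery, vein)
    data, shifts = _acquire(scene, params, rng)
    cube = SpectralCube(data=data, grid=params.grid, stage="raw",
                        provenance={"phantom": "retina", "seed": params.seed})
    truth = PhantomTruth(
        vessel_mask=artery | vein, disc_mask=disc,
        noiseless_cube=SpectralCube(scene, params.grid, stage="corrected",
                                    provenance={"phantom": "retina/noiseless"}),
        params=params, artery_mask=artery, vein_mask=vein, band_shifts=shifts)
    return cube, truth


# ----------------------------------------------------------------- droplets

def generate_droplet_image(aggregate_count: int, speck_radius_px: int,
                           params: PhantomParams
                           ) -> tuple[SpectralCube, list[tuple[int, int]]]:
    """Generate a suspended-droplet acquisition with bright aggregate specks.

    The droplet region carries the tissue reflectance spectrum of
    ``params``; each speck is a small disk with a strongly boosted
    Rayleigh-like scatter term. Vehicle droplets (both amplitudes zero and
    negligible yellowing) have a flat spectrum. Returns the raw cube and
    the speck centers (row, col).
    """
    if aggregate_count < 0 or speck_radius_px < 0:
        raise ValueError("counts and radii must be >= 0")
    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    drop_r = 0.42 * min(h, w)
    droplet = ((yy - cy) ** 2 + (xx - cx) ** 2) <= drop_r ** 2

    place_r = drop_r - speck_radius_px - 2
    if aggregate_count > 0 and place_r <= 0:
        raise ValueError("specks do not fit inside the droplet region")

    spectra = _class_spectra(params)
    speck_params = replace(
        params, oligomer_scatter_amp=(params.oligomer_scatter_amp
                                      + params.speck_scatter_boost))
    speck_spec = params.speck_brightness * params.full_scale * np.asarray(
        tissue_reflectance_model(speck_params, params.grid.wavelengths_nm))
    if params.simulate_bandwidth:
        speck_spec = _smooth_spectrum(speck_spec, params.grid)

    nl = len(params.grid)
    scene = np.full((h, w, nl), 0.02 * params.full_scale, dtype=np.float64)
    scene[droplet] = spectra["tissue"]

    centers: list[tuple[int, int]] = []
    for _ in range(aggregate_count):
        r = place_r * np.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * np.pi)
        py, px = int(round(cy + r * np.sin(th))), int(round(cx + r * np.cos(th)))
        speck = ((yy - py) ** 2 + (xx - px) ** 2) <= speck_radius_px ** 2
        scene[speck & droplet] = speck_spec
        centers.append((py, px))

    data, _ = _acquire(scene, params, rng)
    cube = SpectralCube(data=data, grid=params.grid, stage="raw",
                        provenance={"phantom": "droplet", "seed": params.seed})
    return cube, centers


# ------------------------------------------------------------- instrument

def make_default_instrument_profile(grid: WavelengthGrid) -> InstrumentProfile:
    """A plausible bench-ophthalmoscope profile: ~45% pellicle transmittance
    with a mild spectral slope, and a xenon-like light-input curve peaking
    near 475 nm and rolling off toward the UV."""
    lam = grid.wavelengths_nm
    pellicle = 0.42 + 0.06 * (lam - 320.0) / 360.0
    xenon = 0.6 + 0.6 * np.exp(-(((lam - 470.0) / 90.0) ** 2))
    uv_cut = 0.25 + 0.75 / (1.0 + np.exp(-(lam - 360.0) / 30.0))
    return InstrumentProfile(grid, pellicle, xenon * uv_cut,
                             provenance={"source": "synthetic default"})


def apply_instrument(cube: SpectralCube, profile: InstrumentProfile,
                     quantize: bool = True) -> SpectralCube:
    """Simulate what the camera records before correction: multiply each
    band by pellicle_transmittance * light_input.

    With ``quantize`` (default) the result is rounded to 16-bit counts and
    labelled stage ``raw``; with ``quantize=False`` a float cube is returned
    (exactly invertible by instrument correction).
    """
    if profile.grid != cube.grid:
        raise ValueError("cube and instrument profile grids differ")
    data = cube.data.astype(np.float64) * profile.factors[None, None, :]
    if quantize:
        data = np.clip(np.rint(data), 0, 2 ** cube.bit_depth - 1)
        return SpectralCube(data.astype(np.uint16), cube.grid, stage="raw",
                            bit_depth=cube.bit_depth,
                            provenance={**cube.provenance,
                                        "instrument": "applied"})
    return SpectralCube(data, cube.grid, stage="corrected",
                        provenance={**cube.provenance,
                                    "instrument": "applied (float)"})


# ---------------------------------------------------------------- presets

PRESETS: dict[str, dict] = {
    # wild-type littermate: small intrinsic scatter, no plaque hump
    "wt": {"oligomer_scatter_amp": 0.04, "plaque_scatter_amp": 0.0},
    # young transgenic: strong oligomer (short-wavelength) scatter only
    "tg-young": {"oligomer_scatter_amp": 0.50, "plaque_scatter_amp": 0.0},
    # mid-age: oligomer scatter plus an emerging ~550 nm plaque hump
    "tg-mid": {"oligomer_scatter_amp": 0.45, "plaque_scatter_amp": 0.12},
    # aged: reduced oligomer term, pronounced ~550 nm plaque hump
    "tg-old": {"oligomer_scatter_amp": 0.30, "plaque_scatter_amp": 0.30},
    # in vitro droplets: nearly flat PBS vehicle; the amyloid solution adds
    # Rayleigh-like scatter and a near-UV attenuation (the `lens_yellowing`
    # sigmoid doubles as the solution's short-wavelength cutoff, keeping
    # the 380 nm baseline below the 670 nm reference)
    "droplet-vehicle": {"oligomer_scatter_amp": 0.0, "plaque_scatter_amp": 0.0,
                        "lens_yellowing": 0.05, "vessel_count": 0,
                        "optic_disc_radius_px": 0, "vignette_strength": 0.05},
    "droplet-amyloid": {"oligomer_scatter_amp": 0.35, "plaque_scatter_amp": 0.0,
                        "lens_yellowing": 0.5, "vessel_count": 0,
                        "optic_disc_radius_px": 0, "vignette_strength": 0.05},
}


def preset_params(name: str, seed: int = 0,
                  grid: WavelengthGrid | None = None,
                  **overrides) -> PhantomParams:
    """PhantomParams for a named preset, with optional overrides."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    kw = dict(PRESETS[name])
    kw.update(overrides)
    if grid is not None:
        kw["grid"] = grid
    return PhantomParams(seed=seed, **kw)
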