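"""Core spectral quantification.

Baseline/reference normalization of spectral profiles, per-pixel spectral
Delta maps, group residual profiles with their band normalization, and the
alternate normalization to the mean reflectance across all wavelengths.

The central quantity is the baseline-corrected, reference-normalized
intensity

    norm(lambda) = (I(lambda) - I(lambda_base)) / (I(lambda_ref) - I(lambda_base))

with lambda_base = 380 nm and lambda_ref = 670 nm by default; evaluated
per pixel at the amyloid criterion wavelength lambda_Ab = 475 nm it becomes
the spectral Delta map

    Delta = (I_475 - I_380) / (I_670 - I_380)

whose value sits near 1 for control tissue and rises where short-wavelength
scatter (amyloid-like) is present.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sps

from .core_io import SpectralCube, WavelengthGrid

__all__ = [
    "SpectralProfile", "DeltaMap", "ResidualProfile", "normalize_profile",
    "compute_delta_map", "delta_heatmap", "group_residual",
    "band_normalize_residual", "normalize_to_mean",
]

#: relative tolerance (vs cube dynamic range) below which the Delta
#: denominator is treated as degenerate
DENOM_REL_TOL = 1e-9


@dataclass(frozen=True)
class SpectralProfile:
    """One intensity-vs-wavelength curve for an ROI or whole masked image."""

    grid: WavelengthGrid
    values: np.ndarray
    n_pixels: int | None = None
    normalization: str = "none"  # none | baseline_ref | mean_all
    lambda_base: float | None = None
    lambda_ref: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.grid),):
            raise ValueError("profile length must match its grid")

    def at(self, nm: float, tol_nm: float = 1.0) -> float:
        return float(self.values[self.grid.index_of(nm, tol_nm)])


@dataclass
class DeltaMap:
    """Per-pixel spectral Delta image at the criterion wavelength."""

    values: np.ndarray
    invalid_mask: np.ndarray
    lambda_ab: float
    lambda_base: float
    lambda_ref: float

    def __post_init__(self) -> None:
        if self.values.shape != self.invalid_mask.shape:
            raise ValueError("value and invalid-mask shapes differ")

    def mean(self) -> float:
        """Mean Delta over valid pixels."""
        return float(np.nanmean(self.values[~self.invalid_mask]))


@dataclass
class ResidualProfile:
    """Per-band group difference (A minus B) of mean normalized spectra,
    with the 95% confidence half-width of the reference group B."""

    grid: WavelengthGrid
    residual: np.ndarray
    ci95: np.ndarray
    n_a: int
    n_b: int
    normalization_band: tuple[float, float] | None = None


def normalize_profile(p: SpectralProfile, lambda_base: float = 380.0,
                      lambda_ref: float = 670.0,
                      tol_nm: float = 1.0) -> SpectralProfile:
    """Baseline-correct at lambda_base and normalize to lambda_ref.

    out(lambda) = (p(lambda) - p(base)) / (p(ref) - p(base)); by
    construction out(base) = 0 and out(ref) = 1. Affine-invariant in the
    input. Raises if the two anchor bands coincide in value.
    """
    i_base = p.grid.index_of(lambda_base, tol_nm)
    i_ref = p.grid.index_of(lambda_ref, tol_nm)
    v_base, v_ref = p.values[i_base], p.values[i_ref]
    denom = v_ref - v_base
    if not np.isfinite(denom) or denom == 0:
        raise ValueError(
            f"degenerate normalization: intensity at {lambda_ref} nm equals "
            f"intensity at {lambda_base} nm")
    out = (p.values - v_base) / denom
    return replace(p, values=out, normalization="baseline_ref",
                   lambda_base=lambda_base, lambda_ref=lambda_ref)


def normalize_to_mean(p: SpectralProfile) -> SpectralProfile:
    """Normalize to the average reflectance across all wavelengths.

    A shape-preserving alternative to the baseline/reference scheme: every
    band is divided by the profile mean, so the output mean is exactly 1
    and all band ratios are unchanged. Idempotent.
    """
    m = float(np.nanmean(p.values))
    if m == 0 or not np.isfinite(m):
        raise ValueError("profile mean is zero; cannot normalize")
    return replace(p, values=p.values / m, normalization="mean_all",
                   lambda_base=None, lambda_ref=None)


def compute_delta_map(cube: SpectralCube, lambda_ab: float = 475.0,
                      lambda_base: float = 380.0, lambda_ref: float = 670.0,
                      tol_nm: float = 1.0) -> DeltaMap:
    """Per-pixel spectral Delta = (I_ab - I_base) / (I_ref - I_base).

    Pixels whose denominator magnitude falls below ``DENOM_REL_TOL`` times
    the cube dynamic range — or that are invalid in any of the three bands —
    are flagged in ``invalid_mask`` and carry NaN, never propagated values.
    """
    i_ab = cube.band(lambda_ab, tol_nm)
    i_base = cube.band(lambda_base, tol_nm)
    i_ref = cube.band(lambda_ref, tol_nm)
    data = cube.data
    dyn = float(np.nanmax(data) - np.nanmin(data))
    tol = DENOM_REL_TOL * max(dyn, 1e-300)
    denom = i_ref.astype(float) - i_base.astype(float)
    invalid = (~np.isfinite(i_ab.astype(float))
               | ~np.isfinite(denom)
               | (np.abs(denom) < tol))
    with np.errstate(divide="ignore", invalid="ignore"):
        values = (i_ab.astype(float) - i_base.astype(float)) / denom
    values = np.where(invalid, np.nan, values)
    return DeltaMap(values=values, invalid_mask=invalid, lambda_ab=lambda_ab,
                    lambda_base=lambda_base, lambda_ref=lambda_ref)


def delta_heatmap(dmap: DeltaMap, out_path, vmin: float = 0.5,
                  vmax: float = 2.0, cmap: str = "jet") -> str:
    """Write the Delta map as a color-coded PNG heat map.

    A fixed scale (default [0.5, 2.0]) keeps control tissue (Delta ~ 1) in
    cool colors and amyloid-like tissue (Delta ~ 1.5) in warm colors across
    images; invalid pixels are fully transparent.
    """
    import matplotlib
    import matplotlib.pyplot as plt

    norm = np.clip((dmap.values - vmin) / (vmax - vmin), 0.0, 1.0)
    norm = np.where(dmap.invalid_mask, 0.0, norm)
    rgba = matplotlib.colormaps[cmap](norm)
    rgba[..., 3] = np.where(dmap.invalid_mask, 0.0, 1.0)
    plt.imsave(str(out_path), rgba)
    return str(out_path)


def group_residual(group_a: list[SpectralProfile],
                   group_b: list[SpectralProfile]) -> ResidualProfile:
    """Per-band mean(A) - mean(B), with 95% confidence half-widths of the
    reference group B (t-distribution, n_b - 1 df) to aid visualization."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least two profiles per group")
    grid = group_a[0].grid
    norm = group_a[0].normalization
    for p in (*group_a, *group_b):
        if p.grid != grid:
            raise ValueError("all profiles must share one wavelength grid")
        if p.normalization != norm:
            raise ValueError("profiles mix normalization conventions")
    a = np.vstack([p.values for p in group_a])
    b = np.vstack([p.values for p in group_b])
    n_b = b.shape[0]
    tcrit = sps.t.ppf(0.975, n_b - 1)
    ci95 = tcrit * b.std(axis=0, ddof=1) / np.sqrt(n_b)
    return ResidualProfile(grid=grid, residual=a.mean(axis=0) - b.mean(axis=0),
                           ci95=ci95, n_a=a.shape[0], n_b=n_b)


def band_normalize_residual(r: ResidualProfile,
                            band: tuple[float, float] = (450.0, 475.0)
                            ) -> ResidualProfile:
    """Divide a residual profile by its mean over the closed wavelength band
    (default 450-475 nm), so the band mean becomes exactly 1.

    Scale-invariant and idempotent; puts residuals from different ages and
    preparations on a common short-wavelength scale.
    """
    idx = r.grid.band_indices(*band)
    m = float(r.residual[idx].mean())
    if m == 0 or not np.isfinite(m):
        raise ValueError(f"mean residual over {band} nm is zero")
    return ResidualProfile(grid=r.grid, residual=r.residual / m,
                           ci95=r.ci95 / abs(m), n_a=r.n_a, n_b=r.n_b,
                           normalization_band=band)
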