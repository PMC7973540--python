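"""Data model and I/O for hyperspectral cubes, wavelength grids,
instrument profiles, exclusion masks and ROI tables.

Conventions
-----------
* Cubes are ``H x W x L`` arrays (row-major, 0-based); band ``i`` of a cube
  corresponds to entry ``i`` of its :class:`WavelengthGrid`.
* Cubes travel on disk as multi-page grayscale TIFF stacks (page ``i`` =
  band ``i``, ascending wavelength) with a CSV *sidecar* listing one
  wavelength per page. TIFF tags are not relied upon for the grid.
* Exclusion masks store the *keep* set: 1 = analyse, 0 = excluded
  (vessel / optic-disc) pixel.
* Invalid pixels in floating-point cubes are encoded as NaN; raw 16-bit
  acquisitions have no invalid pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "WavelengthGrid", "SpectralCube", "InstrumentProfile", "ExclusionMask",
    "RoiSpec", "read_cube", "write_cube", "read_instrument_profile",
    "read_mask", "write_mask", "read_roi_table",
]

STAGES = ("raw", "corrected", "registered")

ROI_LABELS = ("with_speck", "no_speck", "vehicle", "retina")


@dataclass(frozen=True)
class WavelengthGrid:
    """Ordered band-center wavelengths (nm) plus the nominal bandwidth.

    The acquisition sweeps narrow-band illumination in 1 nm steps from
    320 to 680 nm (361 bands) with ~10 nm optical bandwidth; decimated
    grids (e.g. 5 nm steps) are supported everywhere for fast simulation.
    """

    wavelengths_nm: np.ndarray
    bandwidth_nm: float = 10.0

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        if wl.ndim != 1 or wl.size < 1:
            raise ValueError("wavelength grid must be a non-empty 1-D array")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if wl.min() < 300 or wl.max() > 800:
            raise ValueError("wavelengths must lie within [300, 800] nm")
        if self.bandwidth_nm <= 0:
            raise ValueError("bandwidth must be positive")

    @classmethod
    def default(cls, bandwidth_nm: float = 10.0) -> "WavelengthGrid":
        """The full acquisition grid: 320..680 nm inclusive, 1 nm steps."""
        return cls(np.arange(320.0, 681.0, 1.0), bandwidth_nm)

    @classmethod
    def decimated(cls, step_nm: float = 5.0,
                  bandwidth_nm: float = 10.0) -> "WavelengthGrid":
        """A coarse grid 320..680 nm in ``step_nm`` steps (must divide 360)."""
        wl = np.arange(320.0, 680.0 + 0.5 * step_nm, step_nm)
        return cls(wl, bandwidth_nm)

    def __len__(self) -> int:
        return int(self.wavelengths_nm.size)

    def index_of(self, nm: float, tol_nm: float = 1.0) -> int:
        """Index of the band nearest ``nm``; error if farther than ``tol_nm``."""
        i = int(np.argmin(np.abs(self.wavelengths_nm - nm)))
        if abs(self.wavelengths_nm[i] - nm) > tol_nm + 1e-12:
            raise KeyError(
                f"no band within {tol_nm} nm of {nm} nm "
                f"(grid spans {self.wavelengths_nm[0]}..{self.wavelengths_nm[-1]})"
            )
        return i

    def band_indices(self, lo_nm: float, hi_nm: float) -> np.ndarray:
        """Indices of all bands with lo_nm <= wavelength <= hi_nm."""
        wl = self.wavelengths_nm
        idx = np.nonzero((wl >= lo_nm - 1e-9) & (wl <= hi_nm + 1e-9))[0]
        if idx.size == 0:
            raise KeyError(f"grid has no bands in [{lo_nm}, {hi_nm}] nm")
        return idx

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return (self.wavelengths_nm.shape == other.wavelengths_nm.shape
                and np.allclose(self.wavelengths_nm, other.wavelengths_nm)
                and self.bandwidth_nm == other.bandwidth_nm)


@dataclass
class SpectralCube:
    """An ``H x W x L`` intensity volume with its wavelength grid.

    ``stage`` tracks provenance: ``raw`` (integer camera counts, 16-bit),
    ``corrected`` (instrument-corrected, float) or ``registered``
    (translation-aligned, float, may contain NaN out-of-field pixels).
    """

    data: np.ndarray
    grid: WavelengthGrid
    stage: str = "raw"
    bit_depth: int = 16
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("cube data must be H x W x L")
        h, w, nb = self.data.shape
        if h < 1 or w < 1:
            raise ValueError("cube spatial dimensions must be >= 1")
        if nb != len(self.grid):
            raise ValueError(
                f"cube has {nb} bands but grid has {len(self.grid)}")
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}")
        if self.stage == "raw":
            if not np.issubdtype(self.data.dtype, np.integer):
                raise ValueError("raw cubes must hold integer counts")
            if self.data.min() < 0 or self.data.max() > 2 ** self.bit_depth - 1:
                raise ValueError("raw counts outside the bit-depth range")
        else:
            self.data = self.data.astype(np.float64, copy=False)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def band(self, nm: float, tol_nm: float = 1.0) -> np.ndarray:
        """The H x W image at the band nearest ``nm``."""
        return self.data[:, :, self.grid.index_of(nm, tol_nm)]

    def subset(self, lo_nm: float, hi_nm: float) -> "SpectralCube":
        """Sub-cube restricted to bands in [lo_nm, hi_nm] (order preserved)."""
        idx = self.grid.band_indices(lo_nm, hi_nm)
        grid = WavelengthGrid(self.grid.wavelengths_nm[idx],
                              self.grid.bandwidth_nm)
        return replace(self, data=self.data[:, :, idx], grid=grid)



@dataclass(frozen=True)
class InstrumentProfile:
    """Per-wavelength pellicle transmittance and relative light input.

    These are the two strictly positive per-band factors whose product
    divides the raw counts during instrument correction (the pellicle
    attenuates the imaging arm; the light-input curve folds together the
    source spectrum and the illumination-arm pellicle reflectance).
    """

    grid: WavelengthGrid
    pellicle_transmittance: np.ndarray
    light_input: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pt = np.asarray(self.pellicle_transmittance, dtype=float)
        li = np.asarray(self.light_input, dtype=float)
        object.__setattr__(self, "pellicle_transmittance", pt)
        object.__setattr__(self, "light_input", li)
        n = len(self.grid)
        if pt.shape != (n,) or li.shape != (n,):
            raise ValueError("profile factors must match the grid length")
        if np.any(pt <= 0) or np.any(pt > 1):
            raise ValueError("pellicle transmittance must lie in (0, 1]")
        if np.any(li <= 0):
            raise ValueError("light input factors must be strictly positive")

    @property
    def factors(self) -> np.ndarray:
        """The per-band product dividing raw counts during correction."""
        return self.pellicle_transmittance * self.light_input

    def interpolated(self, grid: WavelengthGrid) -> "InstrumentProfile":
        """Linear interpolation of both factors onto ``grid``.

        Requested wavelengths must lie inside the tabulated range;
        the resampling is recorded in provenance.
        """
        src = self.grid.wavelengths_nm
        dst = grid.wavelengths_nm
        if dst[0] < src[0] - 1e-9 or dst[-1] > src[-1] + 1e-9:
            raise ValueError("target grid extends beyond the tabulated range")
        pt = np.interp(dst, src, self.pellicle_transmittance)
        li = np.interp(dst, src, self.light_input)
        prov = dict(self.provenance)
        prov["interpolated_from_n_rows"] = int(src.size)
        return InstrumentProfile(grid, pt, li, prov)


@dataclass
class ExclusionMask:
    """Binary keep-mask: 1 = analyse, 0 = excluded (vessel / optic disc)."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2:
            raise ValueError("mask must be 2-D")
        self.mask = m.astype(bool)
        if not self.mask.any():
            raise ValueError("mask excludes every pixel")

    def check_cube(self, cube: SpectralCube) -> None:
        if self.mask.shape != cube.shape[:2]:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match cube "
                f"spatial shape {cube.shape[:2]}")


@dataclass(frozen=True)
class RoiSpec:
    """A square region of interest: top-left (row0, col0), half-open extent
    ``[row0, row0+size) x [col0, col0+size)``. Default 10 x 10 pixels."""

    row0: int
    col0: int
    size: int = 10
    label: str = "retina"

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("ROI size must be >= 1")
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError("ROI origin must be non-negative")
        if self.label not in ROI_LABELS:
            raise ValueError(f"label must be one of {ROI_LABELS}")

    def slices(self) -> tuple[slice, slice]:
        return (slice(self.row0, self.row0 + self.size),
                slice(self.col0, self.col0 + self.size))

    def check_bounds(self, shape: tuple[int, int]) -> None:
        if self.row0 + self.size > shape[0] or self.col0 + self.size > shape[1]:
            raise ValueError(f"ROI {self} exceeds image bounds {shape}")


# ----------------------------------------------------------------- cube I/O

def _read_sidecar(sidecar_path) -> WavelengthGrid:
    df = pd.read_csv(sidecar_path)
    if "wavelength_nm" not in df.columns:
        raise ValueError("sidecar must have a wavelength_nm column")
    if "band_index" in df.columns:
        df = df.sort_values("band_index")
        if not np.array_equal(df["band_index"].to_numpy(),
                              np.arange(len(df))):
            raise ValueError("sidecar band_index must be 0..n-1")
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    if np.any(np.diff(wl) <= 0):
        raise ValueError("sidecar wavelengths must be strictly increasing")
    bw = float(df["bandwidth_nm"].iloc[0]) if "bandwidth_nm" in df.columns else 10.0
    return WavelengthGrid(wl, bw)


def read_cube(stack_path, sidecar_path) -> SpectralCube:
    """Read a multi-page grayscale TIFF stack plus its wavelength sidecar.

    Page ``i`` of the stack becomes band ``i``; the sidecar must list exactly
    one wavelength per page in ascending order.
    """
    grid = _read_sidecar(sidecar_path)
    with tifffile.TiffFile(str(stack_path)) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3:
        raise ValueError("stack pages must be single-channel grayscale")
    if arr.shape[0] != len(grid):
        raise ValueError(
            f"stack has {arr.shape[0]} pages but sidecar lists {len(grid)}")
    meta: dict = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {"description": desc}
    stage = meta.get("stage", "raw")
    bit_depth = int(meta.get("bit_depth", 16))
    data = np.moveaxis(arr, 0, -1)
    if stage == "raw" and not np.issubdtype(data.dtype, np.integer):
        raise ValueError("raw stacks must be integer-typed")
    return SpectralCube(data=data, grid=grid, stage=stage,
                        bit_depth=bit_depth, provenance=meta)


def write_cube(cube: SpectralCube, stack_path, sidecar_path) -> None:
    """Write a cube as a multi-page TIFF stack plus CSV sidecar.

    Raw cubes are stored as 16-bit integers (lossless round-trip);
    corrected/registered cubes as 32-bit float pages.
    """
    pages = np.moveaxis(cube.data, -1, 0)
    if cube.stage == "raw":
        pages = pages.astype(np.uint16)
    else:
        pages = pages.astype(np.float32)
    meta = dict(cube.provenance)
    meta.update(stage=cube.stage, bit_depth=cube.bit_depth)
    tifffile.imwrite(str(stack_path), pages, photometric="minisblack",
                     description=json.dumps(meta, default=str))
    pd.DataFrame({
        "band_index": np.arange(len(cube.grid)),
        "wavelength_nm": cube.grid.wavelengths_nm,
        "bandwidth_nm": cube.grid.bandwidth_nm,
    }).to_csv(sidecar_path, index=False)


def read_instrument_profile(csv_path, grid: WavelengthGrid | None = None
                            ) -> InstrumentProfile:
    """Read an instrument profile table.

    Expects columns ``wavelength_nm``, ``pellicle_transmittance``,
    ``light_input``. If ``grid`` is given and differs from the tabulated
    wavelengths, the factors are linearly interpolated onto it (recorded in
    provenance).
    """
    df = pd.read_csv(csv_path)
    required = {"wavelength_nm", "pellicle_transmittance", "light_input"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"profile table missing columns: {sorted(missing)}")
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    if np.any(np.diff(wl) <= 0):
        raise ValueError("profile wavelengths must be strictly increasing")
    prof = InstrumentProfile(
        WavelengthGrid(wl),
        df["pellicle_transmittance"].to_numpy(dtype=float),
        df["light_input"].to_numpy(dtype=float),
        provenance={"source": str(csv_path)},
    )
    if grid is not None and grid != prof.grid:
        prof = prof.interpolated(grid)
    return prof


def write_instrument_profile(profile: InstrumentProfile, csv_path) -> None:
    pd.DataFrame({
        "wavelength_nm": profile.grid.wavelengths_nm,
        "pellicle_transmittance": profile.pellicle_transmittance,
        "light_input": profile.light_input,
    }).to_csv(csv_path, index=False)


def read_mask(path) -> ExclusionMask:
    """Read a binary keep-mask from a single-page TIFF (nonzero = keep)."""
    arr = tifffile.imread(str(path))
    return ExclusionMask(arr != 0)


def write_mask(mask: ExclusionMask, path) -> None:
    tifffile.imwrite(str(path), mask.mask.astype(np.uint8))


def read_roi_table(csv_path) -> list[RoiSpec]:
    """Read ROI specs from CSV with columns label,row0,col0,size."""
    df = pd.read_csv(csv_path)
    return [RoiSpec(int(r.row0), int(r.col0), int(r.size), str(r.label))
            for r in df.itertuples()]


def write_roi_table(rois: Sequence[RoiSpec], csv_path) -> None:
    pd.DataFrame([{"label": r.label, "row0": r.row0,
                   "col0": r.col0, "size": r.size} for r in rois]
                 ).to_csv(csv_path, index=False)
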