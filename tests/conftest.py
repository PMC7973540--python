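import dataclasses

import numpy as np
import pytest

from retinaspec import (
    ExclusionMask,
    WavelengthGrid,
    apply_instrument,
    correct_intensity,
    generate_phantom_retina,
    make_default_instrument_profile,
    preset_params,
)


@pytest.fixture(scope="session")
def grid5() -> WavelengthGrid:
    """The decimated 5 nm test grid (73 bands, 320-680 nm)."""
    return WavelengthGrid.decimated(5.0)


@pytest.fixture(scope="session")
def instrument(grid5):
    return make_default_instrument_profile(grid5)


@pytest.fixture(scope="session")
def wt_phantom():
    """A small noiseless wild-type retina phantom with ground truth."""
    params = preset_params("wt", seed=7, noise_sd=0.0)
    return generate_phantom_retina(params)


def corrected_masked_cube(preset: str, seed: int = 0, noise_sd: float = 0.0,
                          **overrides):
    """Phantom -> instrument (float path) -> correction -> truth masking."""
    from retinaspec import apply_mask

    params = preset_params(preset, seed=seed, noise_sd=noise_sd, **overrides)
    cube, truth = generate_phantom_retina(params)
    prof = make_default_instrument_profile(params.grid)
    corrected = correct_intensity(
        apply_instrument(cube, prof, quantize=False), prof)
    return apply_mask(corrected, ExclusionMask(truth.keep_mask)), truth


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
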