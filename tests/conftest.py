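import warnings

import numpy as np
import pytest

from bruisebands import (
    AppleSpectralModel,
    BruiseEffect,
    SpectralAxis,
    flat_field,
    make_apple_scene,
)
from bruisebands.pixel_extraction import pca_cube
from bruisebands.workflow import run_key_wavelength_study, run_resolution_study


@pytest.fixture(scope="session")
def axis():
    return SpectralAxis.default()


@pytest.fixture(scope="session")
def model(axis):
    return AppleSpectralModel(axis)


@pytest.fixture(scope="session")
def high_scene(model):
    """One high-impact bruised apple scene used across test modules."""
    return make_apple_scene(model, BruiseEffect.from_severity("high"), seed=3)


@pytest.fixture(scope="session")
def high_cube(high_scene):
    return flat_field(high_scene.raw, high_scene.white, high_scene.dark)


@pytest.fixture(scope="session")
def high_pc(high_scene, high_cube):
    return pca_cube(high_cube, high_scene.truth.apple_mask)


@pytest.fixture(scope="session")
def study():
    """The default key-wavelength study: 24-apple cohort, PCA + SFS."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_key_wavelength_study(seed=1)


@pytest.fixture(scope="session")
def resolution(study):
    """Resolution optimization ranked on the study cohort, evaluated fresh."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_resolution_study(study, eval_seed=2, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
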