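import numpy as np
import pytest

import phenofuel.synthetic_scene as scene
from phenofuel.phenology_fourier import NDVIStack, mean_seasonal_profile, tfa_image


def make_stack(config, class_map=None):
    """NDVIStack from a scene config (helper shared across test modules)."""
    if class_map is None:
        class_map = scene.generate_class_map(config)
    vals = scene.generate_ndvi_stack(class_map, config)
    return NDVIStack(values=vals, transform=config.transform, crs=config.crs,
                     years=list(range(config.n_years)))


def fourier_of(config, class_map=None):
    stack = make_stack(config, class_map)
    return tfa_image(mean_seasonal_profile(stack))


@pytest.fixture(scope="session")
def zero_noise_config():
    """4-class 40x40 block scene with no noise: exact downstream oracles."""
    return scene.default_scene_config(
        40, 40, noise_sd=0.0, year_effect_sd=0.0, n_years=3)


@pytest.fixture(scope="session")
def zero_noise_class_map(zero_noise_config):
    return scene.generate_class_map(zero_noise_config)


@pytest.fixture(scope="session")
def zero_noise_fourier(zero_noise_config, zero_noise_class_map):
    return fourier_of(zero_noise_config, zero_noise_class_map)
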