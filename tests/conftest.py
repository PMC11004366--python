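import numpy as np
import pytest

from grazecap import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def default_scene():
    """The package-default synthetic scene (seed 0), shared across tests."""
    return generate_scene(SceneConfig(seed=0))


@pytest.fixture(scope="session")
def small_noiseless_scene():
    """Small noise-free scene with known calibration (a, b) = (0.1, 0.8)."""
    cfg = SceneConfig(
        seed=5,
        grid_rows=32,
        grid_cols=32,
        years=(2000, 2009),
        modern_start_year=2005,
        noise_sd=0.0,
        sensor_a_intercept=0.1,
        sensor_a_slope=0.8,
        nodata_fraction=0.0,
        n_counties=4,
    )
    return cfg, generate_scene(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
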