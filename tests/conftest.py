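import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import seednet as sn

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_grid():
    return sn.WavelengthGrid(np.linspace(1000.0, 1600.0, 32))


@pytest.fixture(scope="session")
def tiny_cube(small_grid):
    """4 x 5 x 32 reflectance cube with integer-friendly values."""
    rng = np.random.default_rng(7)
    data = rng.uniform(0.1, 0.9, size=(4, 5, 32))
    return sn.SpectralCube(data, small_grid, kind="reflectance")


@pytest.fixture(scope="session")
def tiny_separable():
    """3 classes x 60, 64 bands; zero-overlap class structure."""
    cfg = sn.separable_config(n_classes=3, n_per_class=60, seed=0, n_bands=64)
    data = sn.generate_spectra(cfg)
    split = sn.split_stratified(data.labels, (3, 1, 1), seed=0)
    return data, split


@pytest.fixture(scope="session")
def trained_tiny_vgg(tiny_separable):
    data, split = tiny_separable
    model = sn.build_vgg(data.n_bands, data.n_classes, seed=0)
    fit = sn.train(model, data, split, sn.TrainConfig(epochs=12, batch_size=16, seed=0))
    return model, fit, data, split
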