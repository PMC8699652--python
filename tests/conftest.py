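"""Shared fixtures: small spectral sets and planted-signal benchmarks."""

import numpy as np
import pytest

from oilblend import (
    DesignSpec,
    ScatterNoiseModel,
    SpectrumSet,
    SampleMeta,
    WavelengthGrid,
    generate_dataset,
)


@pytest.fixture(scope="session")
def coarse_grid():
    """A 200-point grid spanning the instrument range, for fast tests."""
    return WavelengthGrid(np.linspace(350.0, 2500.0, 200))


@pytest.fixture(scope="session")
def default_dataset():
    """The full 110-sample design with default noise, seed 0."""
    return generate_dataset(noise=ScatterNoiseModel(seed=0))


@pytest.fixture(scope="session")
def noiseless_dataset(coarse_grid):
    """The full design with all noise off, on the coarse grid."""
    return generate_dataset(
        noise=ScatterNoiseModel(sigma_mult=0, sigma_add=0, sigma_white=0, seed=0),
        grid=coarse_grid,
    )


@pytest.fixture
def tiny_set():
    """A hand-built 3-sample, 5-wavelength SpectrumSet."""
    grid = WavelengthGrid(np.array([400.0, 500.0, 600.0, 700.0, 800.0]))
    refl = np.array([
        [0.2, 0.3, 0.4, 0.5, 0.6],
        [0.25, 0.35, 0.40, 0.55, 0.65],
        [0.1, 0.2, 0.35, 0.45, 0.5],
    ])
    meta = [
        SampleMeta("s1", "sesame_soy", 0.0, 1),
        SampleMeta("s2", "sesame_soy", 0.5, 1),
        SampleMeta("s3", "rapeseed_soy", 1.0, 2),
    ]
    return SpectrumSet(grid=grid, reflectance=refl, meta=meta)


def planted_signal(seed, n=110, p=200, n_informative=10, noise_sd=0.02):
    """Regression data where 10 well-separated columns each carry one of
    the 10 independent latent factors whose sum is the response.

    Returns (X, y, informative column indices).
    """
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, n_informative))
    y = z.sum(axis=1)
    informative = np.linspace(5, p - 6, n_informative).astype(int)
    X = rng.standard_normal((n, p))
    X[:, informative] = z + noise_sd * rng.standard_normal((n, n_informative))
    return X, y, informative
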