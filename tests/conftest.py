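import numpy as np
import pytest

from kpcforest import FeatureMatrix, SpectralBlock, generate_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, names=None, modalities=None, sample_ids=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    names = names or [f"v{j}" for j in range(p)]
    modalities = modalities or ["nmr"] * p
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    return FeatureMatrix(values, names, modalities, sample_ids)


@pytest.fixture
def matrix_factory():
    return make_matrix


@pytest.fixture
def spectral_block(rng):
    n, m = 6, 64
    axis = np.linspace(0.5, 9.5, m)
    base = np.exp(-((axis - 3.0) ** 2) / 0.05) + 0.5 * np.exp(-((axis - 7.0) ** 2) / 0.1)
    dilution = rng.uniform(0.5, 2.0, size=n)
    intensities = dilution[:, None] * (base[None, :] + 0.01 * rng.random((n, m)))
    return SpectralBlock(intensities, axis, [f"s{i}" for i in range(n)])


@pytest.fixture(scope="session")
def tiny_study():
    """Small radial study reused by several test modules."""
    return generate_study(
        n=60, p=12, n_informative=4, n_subjects=4, n_nutrients=6, seed=42
    )
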