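import numpy as np
import pytest

from radscav import SyntheticSpec, generate_feature_table, generate_tumor_volume


@pytest.fixture(scope="session")
def imbalanced_table():
    """100-sample table at the EGFR-like 14% mutant prevalence."""
    return generate_feature_table(
        SyntheticSpec(n_samples=100, n_features=20, n_informative=5,
                      minority_fraction=0.14, effect_size=1.5, seed=42)
    )


@pytest.fixture(scope="session")
def sphere_volume():
    """Noise-free digital sphere of radius 10 voxels."""
    return generate_tumor_volume((32, 32, 32), (10, 10, 10), texture_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def textured_volume():
    return generate_tumor_volume((32, 32, 32), (10, 8, 6), texture_sd=8.0, seed=1)


def random_score_matrix(rng, m=None, n=None):
    m = m or int(rng.integers(1, 11))
    n = n or int(rng.integers(1, 51))
    return rng.random((m, n))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
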