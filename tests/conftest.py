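import numpy as np
import pytest

from spdxfer.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_spd(rng):
    """Factory for random well-conditioned SPD matrices."""

    def make(n: int) -> np.ndarray:
        G = rng.standard_normal((n, n))
        return G @ G.T + n * np.eye(n)

    return make


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small 3-subject synthetic dataset shared across tests."""
    spec = SyntheticSpec(
        n_subjects=3,
        n_channels=4,
        trials_per_class=20,
        samples_per_trial=100,
        seed=11,
    )
    return generate_dataset(spec)
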