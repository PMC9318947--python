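import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from tsmr.simulate import SyntheticConfig, generate_two_sample_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic study at the default conditions (J=65)."""
    return generate_two_sample_dataset(SyntheticConfig(theta=-0.43, seed=42))


@pytest.fixture(scope="session")
def small_dataset():
    """A quick J=20 dataset with palindromes and some scrambled alleles."""
    cfg = SyntheticConfig(
        n_variants=20,
        theta=0.3,
        palindromic_fraction=0.3,
        allele_scramble_fraction=0.25,
        seed=7,
    )
    return generate_two_sample_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
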