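import numpy as np
import pytest

from spectromicrobe.synthetic_neon import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config():
    """A small but structurally complete synthetic study."""
    return SyntheticConfig(
        n_domains=4,
        n_plots_per_domain=5,
        n_cores_per_plot=2,
        asv_richness_pool=60,
        read_depth_range=(3000, 12000),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
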