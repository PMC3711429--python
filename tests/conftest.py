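import numpy as np
import pytest

from fsgene.simulate import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_bundle():
    """A reduced mixed dataset shared by fast structural tests."""
    config = SyntheticConfig(
        seed=42,
        n_per_class={
            "programmed_PRF": 5,
            "pseudogene": 5,
            "sequencing_error": 2,
        },
        noise=0.05,
    )
    return generate_dataset(config)


@pytest.fixture(scope="session")
def default_bundle():
    """The full default-condition dataset (all seven truth classes)."""
    return generate_dataset(SyntheticConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
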