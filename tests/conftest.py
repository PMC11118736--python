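import logging

import numpy as np
import pytest

from lungfat.phantom import PhantomSpec, generate_volume

logging.getLogger("lungfat").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_volume():
    """One deterministic 64x64 phantom volume used across tests."""
    return generate_volume(PhantomSpec(n_slices=12, lung_first=3, lung_last=8, seed=11))


@pytest.fixture(scope="session")
def noiseless_volume():
    return generate_volume(
        PhantomSpec(n_slices=12, lung_first=3, lung_last=8, seed=11, noise_sd=0.0)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
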