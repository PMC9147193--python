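import numpy as np
import pytest

import neumannmri as nm


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene():
    """Noiseless 16x16, 4-coil scene at 2x / 25% ACS."""
    return nm.make_scene(
        rows=16, cols=16, num_coils=4, acceleration=2, acs_fraction=0.25,
        noise_rel=0.0, seed=3,
    )


@pytest.fixture(scope="session")
def noisy_scene():
    """64x64, 4-coil scene at 4x / 8% ACS with the default noise level."""
    return nm.make_scene(
        rows=64, cols=64, num_coils=4, acceleration=4, acs_fraction=0.08, seed=11,
    )


def random_multicoil(rng, coils=4, rows=16, cols=16):
    return rng.standard_normal((coils, rows, cols)) + 1j * rng.standard_normal(
        (coils, rows, cols)
    )
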