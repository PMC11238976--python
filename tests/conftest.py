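import numpy as np
import pytest

from kpiqa import (
    BRAIN_WINDOW,
    DoseNoiseSpec,
    PhantomSpec,
    generate_head_phantom,
    simulate_dose_noise,
    to_eight_bit,
)


@pytest.fixture(scope="session")
def clean_phantom():
    """Default 512x512 synthetic head slice in HU (seed 0)."""
    return generate_head_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def phantom8(clean_phantom):
    """The clean phantom windowed to 8 bits with the brain window."""
    return to_eight_bit(clean_phantom, BRAIN_WINDOW)


@pytest.fixture(scope="session")
def small_phantom():
    """A 256x256 phantom for the fast end-to-end study tests."""
    return generate_head_phantom(PhantomSpec(size=256, n_structures=25, seed=3))


@pytest.fixture(scope="session")
def noisy_ref8(clean_phantom):
    """Reference-dose acquisition of the phantom, windowed to 8 bits."""
    spec = DoseNoiseSpec(ctdi=89.1, seed=101)
    return to_eight_bit(simulate_dose_noise(clean_phantom, spec), BRAIN_WINDOW)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
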