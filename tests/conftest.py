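import numpy as np
import pytest

from renalseg.phantom import PhantomSpec, generate_slice


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_spec():
    """64-px phantom with the standard 160 mm field of view, noiseless."""
    return PhantomSpec.scaled(64, seed=7)


@pytest.fixture
def small_sample(small_spec):
    return generate_slice(small_spec)
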