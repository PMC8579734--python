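import numpy as np
import pytest

from ivimkurt.phantom import PhantomSpec, generate_phantom
from ivimkurt.series import DEFAULT_SCHEME


@pytest.fixture(scope="session")
def scheme():
    return DEFAULT_SCHEME


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_phantom():
    """A small noisy two-class phantom shared by pipeline-level tests."""
    spec = PhantomSpec(shape=(28, 28, 3), lesions_per_class=5, lesion_shape=(3, 3, 1),
                       sigma=0.02, seed=7)
    series, truth = generate_phantom(spec)
    return spec, series, truth
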