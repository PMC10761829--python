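import numpy as np
import pytest

from adstage import AtrophyFeatureExtractor, PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def extractor():
    return AtrophyFeatureExtractor().fit()


@pytest.fixture(scope="session")
def noiseless_phantom():
    """A clean trimodal phantom (levels 0/100/200) with exact ground truth."""
    return generate_phantom(PhantomSpec(seed=11, void_fraction=0.05))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
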