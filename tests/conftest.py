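import numpy as np
import pytest

from spars.experiment import make_fixture


@pytest.fixture(scope="session")
def rank3_fixture():
    """16x16, 12-frame, 3-class phantom with golden-angle radial k-space."""
    return make_fixture("rank3", seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
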