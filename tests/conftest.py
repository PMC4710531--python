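import numpy as np
import pytest

from ogdm.calibrate import default_parameters


@pytest.fixture(scope="session")
def params():
    """Calibrated default model parameters shared across tests."""
    return default_parameters()


@pytest.fixture()
def rng():
    return np.random.default_rng(20160112)
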