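import numpy as np
import pytest

from vetcdiff.protocol import AcquisitionProtocol


@pytest.fixture(scope="session")
def protocol():
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def b_grid(protocol):
    return np.asarray(protocol.b_values, dtype=float)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
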