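import numpy as np
import pytest

from wpgap.domain import build_disk, build_rectangle
from wpgap.params import baseline_params


@pytest.fixture(scope="session")
def disk64():
    return build_disk(R=4.0, n_phi=64, n_r=64)


@pytest.fixture(scope="session")
def disk128():
    return build_disk(R=4.0, n_phi=128, n_r=64)


@pytest.fixture(scope="session")
def rect64():
    return build_rectangle(Lx=5.0, Ly=5.0, n_x=64, n_y=64)


@pytest.fixture(scope="session")
def base():
    return baseline_params()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
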