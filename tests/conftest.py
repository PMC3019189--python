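import numpy as np
import pytest

from hmmtrain.models import (
    build_dishonest_casino,
    build_extended_casino,
    build_cpg_model,
    build_toy1,
    build_toy2,
)


@pytest.fixture(scope="session")
def toy1():
    return build_toy1()


@pytest.fixture(scope="session")
def toy2():
    return build_toy2()


@pytest.fixture(scope="session")
def casino():
    return build_dishonest_casino()


@pytest.fixture(scope="session")
def extended_casino():
    return build_extended_casino()


@pytest.fixture(scope="session")
def cpg():
    return build_cpg_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
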