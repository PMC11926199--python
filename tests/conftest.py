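import numpy as np
import pytest

from rp2gauge.atlas import build_atlas


@pytest.fixture(scope="session")
def atlas_r1():
    return build_atlas(1)


@pytest.fixture(scope="session")
def atlas_r2():
    return build_atlas(2)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
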