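import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20210341)


@pytest.fixture(scope="session")
def small_bank():
    from srfield import lifting

    return lifting.build_cake_bank(64, 8)
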