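import numpy as np
import pytest

import fossilclock as fc


@pytest.fixture(scope="session")
def small_bundle():
    """One shared small synthetic study (15 taxa, 5 fossils, 800 bp)."""
    return fc.make_pine_fixture("small", seed=3)


@pytest.fixture(scope="session")
def paper_bundle():
    """The paper-shaped study bundle (115 taxa, 21 fossils, ~5.9 kb)."""
    return fc.make_pine_fixture("paper_shaped", seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
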