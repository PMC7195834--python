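import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def path_areas():
    from vicarange.diva import AreaSystem

    return AreaSystem(list("abcd"), [("a", "b"), ("b", "c"), ("c", "d")])
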