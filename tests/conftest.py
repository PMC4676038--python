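import numpy as np
import pytest

from shgvernier import CollectionCone, derive_beam


@pytest.fixture(scope="session")
def beam():
    """Default illumination: 0.850 um, NA 0.8 objective, aqueous medium."""
    return derive_beam(0.850, 0.8, 0.55, 1.33)


@pytest.fixture(scope="session")
def cone():
    """Default forward collection cone, condenser NA 0.55."""
    return CollectionCone(na=0.55)


@pytest.fixture()
def rng():
    return np.random.default_rng(20151211)
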