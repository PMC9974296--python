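import numpy as np
import pytest

from gorget.colour_vision import VisualSystem


@pytest.fixture(scope="session")
def uvs():
    """Default UVS visual system on a 1 nm grid."""
    return VisualSystem.uvs_template()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
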