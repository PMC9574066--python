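import numpy as np
import pytest

from neurocfc.montage import standard_positions


@pytest.fixture(scope="session")
def montage28():
    """Full default montage: (names, positions in cm)."""
    return standard_positions()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
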