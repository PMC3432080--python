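import numpy as np
import pytest

from serprot.motifs import load_reference_anchors


@pytest.fixture(scope="session")
def anchors():
    return load_reference_anchors()


@pytest.fixture()
def rng():
    return np.random.default_rng(20120831)
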