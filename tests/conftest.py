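import numpy as np
import pytest

from zigcusum import ZIGParams


@pytest.fixture
def params_small():
    """Low-mean process used throughout the tabulated studies."""
    return ZIGParams(theta=1.0, p=0.1, alpha=0.5, beta=0.5)


@pytest.fixture
def params_crime():
    """Parameters fitted to the drug-crime case-study series."""
    return ZIGParams(theta=2.0495, p=0.185, alpha=0.547, beta=0.5188)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
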