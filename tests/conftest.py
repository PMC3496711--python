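import numpy as np
import pytest

from fret_ensemble.forster_core import ForsterSystem


@pytest.fixture
def system() -> ForsterSystem:
    """The reference donor-acceptor system: tau0D = 3 ns, R0 = 5.4 nm."""
    return ForsterSystem(tau0D=3.0, R0=5.4)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
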