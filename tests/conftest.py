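import numpy as np
import pytest

from elscape.mem import MEMParameters


def random_params(seed: int, n: int, scale: float = 0.5) -> MEMParameters:
    """Random fields and couplings with entries uniform in [-scale, scale]."""
    rng = np.random.default_rng(seed)
    h = rng.uniform(-scale, scale, size=n)
    J = rng.uniform(-scale, scale, size=(n, n))
    J = 0.5 * (J + J.T)
    np.fill_diagonal(J, 0.0)
    return MEMParameters(h=h, J=J)


@pytest.fixture
def ferromagnet9() -> MEMParameters:
    """h = 0, strong uniform positive couplings: two ground states (all ±1)."""
    n = 9
    J = np.full((n, n), 0.6)
    np.fill_diagonal(J, 0.0)
    return MEMParameters(h=np.zeros(n), J=J)


@pytest.fixture
def strong_field9() -> MEMParameters:
    """h_i = 3, J = 0: monotone landscape with the all-(+1) global minimum."""
    n = 9
    return MEMParameters(h=np.full(n, 3.0), J=np.zeros((n, n)))
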