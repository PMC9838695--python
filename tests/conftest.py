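import numpy as np
import pytest

from ctrlbridge import GaussianState, LinearSystem, make_random_stable_system


@pytest.fixture
def scalar_system() -> LinearSystem:
    """1-D OU with relaxation rate 1 and noise rate 2 (unit stationary variance)."""
    return LinearSystem(np.array([[-1.0]]), np.array([[2.0]]))


@pytest.fixture
def small_system() -> LinearSystem:
    return make_random_stable_system(3, sparsity=0.3, seed=42)


@pytest.fixture
def zero_state():
    def _make(n: int) -> GaussianState:
        return GaussianState(np.zeros(n), np.eye(n))

    return _make
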