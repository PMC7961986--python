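import numpy as np
import pytest

from qmritk.dce_relaxometry import AIFCurve, population_aif
from qmritk.dwi_models import DEFAULT_B_VALUES


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def b_values():
    return DEFAULT_B_VALUES.copy()


@pytest.fixture
def dce_times():
    """50 phases at 8 s temporal resolution."""
    return np.arange(50) * 8.0


@pytest.fixture
def aif(dce_times) -> AIFCurve:
    """Population AIF with bolus arrival at 40 s (5 baseline phases)."""
    return population_aif(dce_times, t0=40.0)
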