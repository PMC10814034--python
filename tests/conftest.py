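import numpy as np
import pytest

from sirwaves import SIRParams, WaveM3


@pytest.fixture(scope="session")
def basic_params() -> SIRParams:
    """The basic tanh-pulse wave: N=1e7, S0=9,999,999, tau=0.00825, rho=0.00775."""
    return SIRParams(N=1e7, tau=0.00825, rho=0.00775, S0=9_999_999.0, I0=1.0)


@pytest.fixture(scope="session")
def basic_m3() -> WaveM3:
    """The basic cubic-family wave: N=1e6, S0=900,000, tau=0.009 (rho implied)."""
    return WaveM3(N=1e6, S0=9e5, tau=0.009)


@pytest.fixture(scope="session")
def basic_grid(basic_params) -> np.ndarray:
    """Uniform grid covering the basic wave well past its peak (~2.2e4)."""
    return np.linspace(0.0, 60_000.0, 40_001)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20231219)
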