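import numpy as np
import pytest

from viscogel.design import CellSensingWindow
from viscogel.mechanics import ASLSParams, LoadingProtocol
from viscogel.transport import GridSpec, TransportParams


@pytest.fixture
def ref_params() -> ASLSParams:
    """The worked example used throughout: tau_rel = 10 s, E_inst = 2 kPa."""
    return ASLSParams(E0=1000.0, E1=1000.0, eta1=10000.0, eta2=0.0, phi=0.0)


@pytest.fixture
def ref_protocol() -> LoadingProtocol:
    return LoadingProtocol(strain_rate=0.01, t_end=60.0, n_samples=301, strain_limit=0.05)


@pytest.fixture
def transport_params() -> TransportParams:
    return TransportParams(r_h=1e-9, kappa=1e-14, mu=1e-3, T=298.15, p=0.95, alpha=0.65)


@pytest.fixture
def small_grid() -> GridSpec:
    """1 mm box resolved along x only; cheap but exercises the full 3-D stencil."""
    return GridSpec(extents=(1e-3, 1e-3, 1e-3), n=(21, 3, 3))


@pytest.fixture
def adsc_window() -> CellSensingWindow:
    return CellSensingWindow(tau_b=1.0, tau_L_min=10.0, tau_L_max=100.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
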