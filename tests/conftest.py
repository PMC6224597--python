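import numpy as np
import pytest

from corset.vertex import EnergyParams, build_tube, calibrate_alpha_wt


@pytest.fixture(scope="session")
def wt_mesh():
    """Default wild-type tube mesh (10 cells/ring x 16 rings)."""
    return build_tube()


@pytest.fixture(scope="session")
def small_mesh():
    """Small mesh for fast relaxation tests."""
    return build_tube(n_circ=10, n_axial=6)


@pytest.fixture(scope="session")
def alpha_wt():
    """Calibrated wild-type contractility at psi = 0.38 (session-cached)."""
    return calibrate_alpha_wt(psi=0.38, target_ratio=0.56)


@pytest.fixture(scope="session")
def wt_params(alpha_wt):
    return EnergyParams(alpha=alpha_wt, psi=0.38)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
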