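import numpy as np
import pytest

from bicellix import (
    BicelleParams,
    RibbonParams,
    SASCurve,
)


@pytest.fixture
def q_mid() -> np.ndarray:
    """Log-spaced grid over the mid-q range used for model fits."""
    return np.geomspace(0.01, 0.5, 120)


@pytest.fixture
def bicelle_5045() -> BicelleParams:
    """Bicelle with total radius 50 A and total height 45 A."""
    return BicelleParams(r_core=38.6, h_tail=28.8, h_head=8.1, delta_r=11.4, scale=3.0e7)


@pytest.fixture
def ribbon_330() -> RibbonParams:
    """Ribbons-only parameter set: core semi-axes 20/43 A, length 330 A."""
    return RibbonParams(r_minor=20.0, r_major=43.0, length=330.0, t_shell=11.4, scale=3.0e7)


@pytest.fixture
def simple_curve() -> SASCurve:
    q = np.geomspace(0.01, 0.3, 50)
    i = 5.0 * q**-1.5
    return SASCurve(q, i, 0.02 * i, label="simple")
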