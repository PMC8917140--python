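import numpy as np
import pytest

from stoprace.generative import DDMParams, ExGaussParams, RaceParams


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def control_race_params():
    """Race parameters at the classical/Control published group values, with
    the calibrated go side."""
    return RaceParams(
        go=ExGaussParams(mu=359.9, sigma=60.1, tau=86.1),
        stop=ExGaussParams(mu=109.0, sigma=36.0, tau=34.0),
        tf=0.0513, gf=0.0028, max_rt=1200.0,
    )


@pytest.fixture
def control_ddm_params():
    """Diffusion parameters at the classical/Control published values."""
    return DDMParams(a=1.78, v=4.00, t0=224.0, z=0.51)
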