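import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import balwave as bw

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_params():
    """Small, fast parameter set for unit tests of individual operations."""
    return bw.ModelParams(
        D0=1e-3, D1=10.0, k_bind=0.1, k_swell=2e-6, f_swell=4.0, theta=0.5,
        m_total=1.0, u_res=1.0, L=6.0, n_cells=60,
        t_end=1e5, dt_out=1e4,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
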