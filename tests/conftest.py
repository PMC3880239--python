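import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import caspike as cp

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def fparams():
    return cp.FilterParams(9, 5)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_bump_trace(apex_index=50, n=120, amplitude=3.0, baseline=1.0,
                    dt=5.0, fparams=cp.FilterParams(9, 5)):
    """Noiseless single asymmetric bump, filtered; returns (raw, trace)."""
    t = np.arange(n) * dt
    onset = apex_index * dt - cp.kernel_apex_time(5.0, 20.0)
    raw = baseline + cp.peak_kernel_value(t - onset, 5.0, 20.0, amplitude)
    return raw, cp.filter_trace(raw, fparams, dt)
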