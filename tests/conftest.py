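import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from wristssr.preprocessing import PeriodStack
from wristssr.signal_design import build_default_spec


@pytest.fixture(scope="session")
def default_spec():
    return build_default_spec(0)


def make_stack(data, fs=None, period_s=1.25, task="passive", labels=None):
    """PeriodStack from an (E, P, N) array with consistent bookkeeping."""
    data = np.asarray(data, float)
    e, p, n = data.shape
    fs = fs if fs is not None else n / period_s
    labels = labels or tuple(f"ch{i}" for i in range(e))
    return PeriodStack(
        data=data, electrode_labels=tuple(labels), sample_rate_hz=fs,
        period_s=period_s, task=task, kept_period_index=np.arange(p),
        period_start_sample=np.arange(p) * n)


@pytest.fixture
def stack_factory():
    return make_stack
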