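import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import vasosim as vs

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def ref_kernel():
    return vs.make_reference_kernel()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_baseline():
    return vs.generate_baseline()


def brute_force_superpose(kernel, schedule, duration):
    """Independent double-loop oracle for linear waveform superposition."""
    dose = schedule.bolus + schedule.infusion
    out = np.zeros(duration + 1)
    for t in range(duration + 1):
        for s in range(t + 1):
            dt = t - s
            f = kernel.values[dt] if dt < kernel.values.size else 0.0
            out[t] += dose[s] * f
    return out
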