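import numpy as np
import pytest

from mitocal import simulate
from mitocal.kinetics import FluorescenceTrace, KineticsConfig

#: the canonical noiseless transient used throughout: f0=100, application at
#: 30 s, 14 s latency, 245 fau/s rise for 10 s, 60 s recovery constant
CANONICAL = simulate.TraceParams(
    baseline_f0=100.0, t_app=30.0, latency=14.0, rise_slope=245.0,
    rise_duration=10.0, decay_tau=60.0, duration=400.0, dt=0.5, noise_sd=0.0,
)


@pytest.fixture(scope="session")
def canonical_params():
    return CANONICAL


@pytest.fixture(scope="session")
def canonical_trace():
    return simulate.simulate_trace(CANONICAL)


@pytest.fixture
def constant_trace():
    t = np.arange(0, 100, 0.5)
    return FluorescenceTrace(time=t, fluorescence=np.full_like(t, 100.0), t_app=30.0)


@pytest.fixture(scope="session")
def default_config():
    return KineticsConfig()
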