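import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def sinusoid():
    """Noiseless sinusoid, period 24 samples, N = 200 (peaks at 6, 30, ..., 198)."""
    t = np.arange(200)
    return np.sin(2 * np.pi * t / 24)


@pytest.fixture
def pulse_trace():
    """Default pulsatile phantom diameter trace: 6/min, 30% depth, 3 min at 2.5/s."""
    from nirlymph.phantom import ContractionWaveformParams, generate_traces

    wave = ContractionWaveformParams()
    return generate_traces(wave, "diameter")
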