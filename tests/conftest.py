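import numpy as np
import pytest

from speedpeaks import PipelineConfig, SimConfig, make_kernel, synth_recording


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def kernel25():
    return make_kernel(25)


@pytest.fixture(scope="session")
def noiseless_rec5():
    """5-cycle noiseless synthetic recording with ground truth."""
    return synth_recording(SimConfig(n_cycles=5))


@pytest.fixture
def make_uniform_recording():
    """Factory for simple straight-line recordings on a uniform 240 Hz grid."""

    def _make(n=100, vx=0.0, vy=0.0, vz=0.0, sample_rate=240.0, **kwargs):
        t = np.arange(n) / sample_rate
        pos = np.column_stack([vx * t, vy * t, vz * t])
        from speedpeaks import Recording

        return Recording(time=t, position=pos, sample_rate=sample_rate, **kwargs)

    return _make
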