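import numpy as np
import pytest

from sonophys.acoustics import Modality, StimProtocol
from sonophys.traces import Trace


@pytest.fixture
def us_protocol_dc100():
    return StimProtocol(modality=Modality.US, p_rms=20.0, duty_cycle=1.0)


@pytest.fixture
def us_protocol_dc5():
    return StimProtocol(modality=Modality.US, p_rms=8.0, duty_cycle=0.05)


@pytest.fixture
def flat_trace():
    """5 s of quiet membrane at -40 mV, 10 kHz, one DC=1 stimulation at 1 s."""
    rng = np.random.default_rng(42)
    samples = -40.0 + 0.5 * rng.standard_normal(50_000)
    protocol = StimProtocol(modality=Modality.US, p_rms=20.0, duty_cycle=1.0, isi=1.0)
    return Trace(
        sampling_rate=10.0,
        samples=samples,
        stim_events=[(1000.0, protocol)],
        cell_id="flat",
    )


def make_trace(samples, rate=10.0, events=(), **kwargs):
    return Trace(
        sampling_rate=rate,
        samples=np.asarray(samples, dtype=float),
        stim_events=list(events),
        **kwargs,
    )
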