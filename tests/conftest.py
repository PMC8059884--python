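import numpy as np
import pytest

from glomdyn.trace import OdorEvent, StimulusProtocol, Trace, as_events

RATE = 150.0


@pytest.fixture
def rate():
    return RATE


@pytest.fixture
def single_inhalation():
    """One inhalation at t = 2 s with a 4-s odor presentation around it."""
    protocol = StimulusProtocol([OdorEvent("ester", 2.0, 6.0)])
    return as_events([2.0]), protocol


def make_trace(values, rate=RATE, t0=0.0, units="dFF"):
    return Trace(np.asarray(values, dtype=float), rate, t0, units=units)
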