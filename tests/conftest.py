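import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from esokin import AxisTrace, Session, SensorRecording

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_session(n=5000, rate=500.0, seed=0, units="mG", genre="FPS",
                 dpi=400, participant_id="p01"):
    """Small valid session filled with reproducible noise."""
    rng = np.random.default_rng(seed)
    recs = {}
    for placement in ("hand", "forearm", "arm"):
        traces = {
            a: AxisTrace(rng.normal(0, 5, n), axis=a, units=units, rate=rate)
            for a in "xyz"
        }
        recs[placement] = SensorRecording(placement=placement, **traces)
    return Session(participant_id=participant_id, genre=genre, dpi=dpi, **recs)


@pytest.fixture
def small_session():
    return make_session()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
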