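import numpy as np
import pytest

from ripplescreen.evaluation import DETECTION_FIXTURE, run_detection
from ripplescreen.synthetic import LFPSimParams, simulate_lfp_session


@pytest.fixture(scope="session")
def planted_session():
    """One synthetic session with planted SWRs (~630 s qualified immobility)."""
    params = LFPSimParams(seed=11, ripple_rate_hz=0.2, ripple_amp_sd=8.0,
                          **DETECTION_FIXTURE)
    session, truth = simulate_lfp_session(params)
    return session, truth


@pytest.fixture(scope="session")
def detected(planted_session):
    """(events, immobility, stats) from the shared planted session."""
    session, _ = planted_session
    return run_detection(session)
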