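import numpy as np
import pytest

from patchkin import (
    IdealizedPath,
    RecordingTrace,
    SimConfig,
    StimulusProtocol,
    load_profile,
    simulate_recording,
)


@pytest.fixture(scope="session")
def wt():
    return load_profile("WT")


@pytest.fixture(scope="session")
def wt_recording(wt):
    """One 20 s WT cell-attached recording at -30 mmHg with its true path."""
    protocol = StimulusProtocol.constant(-30.0, 20_000.0)
    config = SimConfig(duration_ms=20_000.0, seed=7)
    trace, paths = simulate_recording(wt, protocol, config)
    return trace, paths[0]


@pytest.fixture
def square_path():
    """Deterministic shut/open alternation: 10 ms shut, 20 ms open, 10 ms shut."""
    return IdealizedPath(
        states=np.array(["shut", "open", "shut"], dtype=object),
        start_ms=np.array([0.0, 10.0, 30.0]),
        duration_ms=np.array([10.0, 20.0, 10.0]),
        level_pA=np.array([0.0, -1.5, 0.0]),
        censored_first=False,
        censored_last=False,
    )


def make_trace(samples, fs=10_000.0, **meta):
    return RecordingTrace(np.asarray(samples, float), sampling_rate_hz=fs, meta=meta)
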