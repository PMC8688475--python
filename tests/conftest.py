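import numpy as np
import pytest

from fiberphot import (
    AnalysisParameters,
    EventStream,
    RecordingSession,
    SynthParams,
    TimeSeries,
    generate_session,
    write_session,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_session(tmp_path):
    """Minimal well-formed generic-CSV session folder at 10 Hz."""
    folder = tmp_path / "tiny"
    folder.mkdir()
    (folder / "control.csv").write_text("timestamps,data\n0,1\n0.1,1\n0.2,1\n")
    (folder / "signal.csv").write_text("timestamps,data\n0,2\n0.1,2\n0.2,2\n")
    (folder / "rewarded.csv").write_text("timestamps\n0.1\n")
    return folder


@pytest.fixture
def clean_session():
    """5 min, 20 Hz session with event-locked transients and no artifacts."""
    params = SynthParams(
        duration=300.0,
        rate=20.0,
        behavioral_events={"reward": tuple(np.arange(20.0, 290.0, 15.0))},
        event_response_latency=1.0,
        noise_sd=0.002,
        seed=7,
    )
    return generate_session(params)


@pytest.fixture
def uniform_ts():
    def make(n=1000, rate=20.0, values=None):
        if values is not None:
            values = np.asarray(values, float)
            n = len(values)
        t = np.arange(n) / rate
        v = np.zeros(n) if values is None else values
        return TimeSeries(t, v, rate)

    return make


@pytest.fixture
def session_folder_factory(tmp_path):
    """Write a synthetic session to disk and return its folder."""

    def make(name="sess", seed=0, **kwargs):
        params = SynthParams(seed=seed, **kwargs)
        session, truth = generate_session(params)
        folder = tmp_path / name
        write_session(session, folder, format="generic_csv")
        return folder, session, truth

    return make
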