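import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def physio_recording():
    """One default control-regime recording (300 s at 250 Hz), coupled."""
    from cardionet.synthetic import simulate_physio_recording

    return simulate_physio_recording(seed=7)


@pytest.fixture(scope="session")
def physio_ridges(physio_recording):
    """Cardiac (ECG and perfusion) and respiratory ridges of the fixture."""
    from cardionet.preprocess import extract_component_phase

    rec = physio_recording
    return {
        "ecg": extract_component_phase(rec.channel("ecg"), 250.0, (0.6, 2.0)),
        "breathing": extract_component_phase(rec.channel("breathing"), 250.0, (0.145, 0.6)),
        "pulse": extract_component_phase(rec.channel("perfusion"), 250.0, (0.6, 2.0)),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
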