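import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

import sdppg
from sdppg import simulate as S


@pytest.fixture(scope="session")
def mid_template():
    return S.BeatTemplate.from_stiffness(0.4)


@pytest.fixture(scope="session")
def clean_recording(mid_template):
    """Noise-, jitter- and drift-free recording (deterministic beats)."""
    spec = S.RecordingSpec(n_beats=28, period_jitter=0.0, drift_rel=0.0,
                           seed=7)
    return S.generate_recording(mid_template, spec)


@pytest.fixture(scope="session")
def noisy_recording(mid_template):
    """Recording at a 25 dB AC signal-to-noise ratio, default jitter/drift."""
    nr = S.noise_rel_for_snr_db(mid_template, 25.0)
    spec = S.RecordingSpec(n_beats=28, noise_rel=nr, seed=11)
    return S.generate_recording(mid_template, spec)


@pytest.fixture(scope="session")
def clean_analysis(clean_recording):
    sig, ann = clean_recording
    return sdppg.analyze_signal(sig), ann


@pytest.fixture(scope="session")
def noisy_analysis(noisy_recording):
    sig, ann = noisy_recording
    return sdppg.analyze_signal(sig), ann
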