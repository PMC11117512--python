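import numpy as np
import pytest

from pulseabi import (
    Channel,
    SampledSignal,
    Side,
    SynthSettings,
    generate_session,
    load_table1,
)


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def clean_session():
    """Default clean study condition: 60 bpm, 90 s, PTTh 0.20 s, PTTf 0.30 s, H=1.7."""
    settings = SynthSettings(seed=11)
    session, truth = generate_session(settings, 1.7, Side.RIGHT)
    return session, truth, settings


@pytest.fixture(scope="session")
def noisy_session():
    """Same condition with 50 Hz hum at QRS amplitude and 10 dB SNR white noise."""
    settings = SynthSettings(seed=11, mains_amp=1.0, snr_db=10.0)
    session, truth = generate_session(settings, 1.7, Side.RIGHT)
    return session, truth, settings


def sine_signal(freq_hz, fs=200.0, duration_s=10.0, channel=Channel.ECG):
    t = np.arange(int(duration_s * fs)) / fs
    return SampledSignal(np.sin(2 * np.pi * freq_hz * t), channel, Side.RIGHT, fs)
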