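import numpy as np
import pytest
from hypothesis import settings

from easim.core import Waveform
from easim.synth_corpus import Corpus

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def corpus44() -> Corpus:
    """Default-rate corpus, as used for the experiment proper."""
    return Corpus(seed=0, rate=44_100)


@pytest.fixture(scope="session")
def corpus32() -> Corpus:
    """Reduced-rate corpus for the audio-heavy observer tests."""
    return Corpus(seed=0, rate=32_000)


def steady_tone_gain_db(filter_fn, freq_hz: float, rate: int = 44_100,
                        duration_s: float = 2.0) -> float:
    """Measured steady-state gain of a filter at one frequency.

    Uses a raised-cosine-gated tone and discards the first half of the
    output, so onset-transient ringing does not leak into the stop-band
    measurement.
    """
    n = int(duration_s * rate)
    t = np.arange(n) / rate
    x = np.sin(2 * np.pi * freq_hz * t)
    ramp = int(0.1 * rate)
    env = np.ones(n)
    env[:ramp] = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
    env[-ramp:] = env[:ramp][::-1]
    wave = Waveform(x * env, rate)
    out = filter_fn(wave)
    lo, hi = int(0.5 * duration_s * rate), int(0.85 * duration_s * rate)
    out_rms = np.sqrt(np.mean(out.samples[lo:hi] ** 2))
    in_rms = np.sqrt(np.mean(wave.samples[lo:hi] ** 2))
    return 20.0 * np.log10(max(out_rms, 1e-12) / in_rms)
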