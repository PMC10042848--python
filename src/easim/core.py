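"""Core time-domain container and small signal utilities.

Everything downstream (vocoder, residual-hearing filters, binaural
renderer, corpus synthesis) passes audio around as :class:`Waveform` —
a mono sample array plus a sample rate.  The default rate of 44.1 kHz
comfortably exceeds twice the highest sine carrier used by the
simulated processors (~11.8 kHz).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_RATE = 44_100
#: digital RMS that stands in for the experiment's fixed 65 dBA target level
REFERENCE_RMS = 0.05


@dataclass(frozen=True)
class Waveform:
    """A mono audio signal: finite float samples at a fixed sample rate."""

    samples: np.ndarray
    rate: int = DEFAULT_RATE

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=np.float64)
        if s.ndim != 1:
            raise ValueError(f"Waveform samples must be 1-D, got shape {s.shape}")
        if s.size and not np.all(np.isfinite(s)):
            raise ValueError("Waveform samples must be finite")
        if self.rate <= 0:
            raise ValueError(f"sample rate must be positive, got {self.rate}")
        object.__setattr__(self, "samples", s)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate

    def rms(self) -> float:
        if not self.samples.size:
            return 0.0
        return float(np.sqrt(np.mean(self.samples**2)))

    def scaled(self, gain: float) -> "Waveform":
        return Waveform(self.samples * float(gain), self.rate)

    def with_rms(self, target_rms: float) -> "Waveform":
        """Rescale to a given long-term RMS; raises on silent input."""
        r = self.rms()
        if r == 0.0:
            raise ValueError("cannot level-match a silent waveform")
        return self.scaled(target_rms / r)


def require_same_grid(a: Waveform, b: Waveform) -> None:
    """Raise unless two waveforms share sample rate and length."""
    if a.rate != b.rate:
        raise ValueError(f"sample-rate mismatch: {a.rate} vs {b.rate}")
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")


def db(power_ratio: float) -> float:
    """10*log10 on a power ratio."""
    return 10.0 * np.log10(power_ratio)


def amp_db(amplitude_ratio: float) -> float:
    """20*log10 on an amplitude (RMS) ratio."""
    return 20.0 * np.log10(amplitude_ratio)


def pure_tone(freq_hz: float, duration_s: float, rate: int = DEFAULT_RATE,
              amplitude: float = 1.0, phase: float = 0.0) -> Waveform:
    t = np.arange(int(round(duration_s * rate))) / rate
    return Waveform(amplitude * np.sin(2 * np.pi * freq_hz * t + phase), rate)


def silence(duration_s: float, rate: int = DEFAULT_RATE) -> Waveform:
    return Waveform(np.zeros(int(round(duration_s * rate))), rate)


def fractional_delay(x: Waveform, delay_s: float) -> Waveform:
    """Delay a signal by a (possibly fractional) number of samples.

    Implemented as a linear phase shift in the frequency domain after
    zero-padding, so no energy wraps around and sub-sample delays are
    exact for band-limited content.  Output is padded by the integer
    ceiling of the delay; callers align lengths afterwards.
    """
    if delay_s < 0:
        raise ValueError("delay must be non-negative")
    n_pad = int(np.ceil(delay_s * x.rate)) + 1
    n = len(x) + n_pad
    spec = np.fft.rfft(x.samples, n)
    freqs = np.fft.rfftfreq(n, d=1.0 / x.rate)
    spec *= np.exp(-2j * np.pi * freqs * delay_s)
    return Waveform(np.fft.irfft(spec, n), x.rate)


def pad_to(x: Waveform, n: int) -> Waveform:
    """Zero-pad (or truncate) to exactly ``n`` samples."""
    if len(x) >= n:
        return Waveform(x.samples[:n], x.rate)
    out = np.zeros(n)
    out[: len(x)] = x.samples
    return Waveform(out, x.rate)
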