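"""Simulated residual acoustic hearing and electric-acoustic summation.

Residual hearing is modeled as a steep band-pass (default 100-600 Hz,
240 dB/octave skirts) applied to the per-ear mixture — no hearing-loss
or recruitment simulation, so this is a best-case acoustic path.  The
240 dB/oct slope is realized as a cascade of a 40th-order Butterworth
high-pass and a 40th-order Butterworth low-pass, each designed directly
in second-order-section form; a direct-form realization of this order
would be numerically unusable.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal

from .core import Waveform, require_same_grid

__all__ = ["AcousticBand", "residual_filter", "combine_eas"]


@dataclass(frozen=True)
class AcousticBand:
    """A residual-hearing passband with a per-edge roll-off slope."""

    low_hz: float = 100.0
    high_hz: float = 600.0
    slope_db_per_oct: float = 240.0

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError(f"need 0 < low < high, got ({self.low_hz}, {self.high_hz})")
        if self.slope_db_per_oct < 6:
            raise ValueError("slope must be at least 6 dB/octave (one filter order)")

    @property
    def order_per_edge(self) -> int:
        """Butterworth order per skirt: 6 dB/octave per order."""
        return max(1, int(round(self.slope_db_per_oct / 6.0)))


@lru_cache(maxsize=32)
def _band_sos(low_hz: float, high_hz: float, order: int, rate: int):
    nyq = rate / 2.0
    if high_hz >= nyq:
        raise ValueError(f"band edge {high_hz} Hz is at or above Nyquist ({nyq} Hz)")
    hp = signal.butter(order, low_hz, btype="highpass", fs=rate, output="sos")
    lp = signal.butter(order, high_hz, btype="lowpass", fs=rate, output="sos")
    sos = np.vstack([hp, lp])
    # Stability check on every biquad: poles strictly inside the unit circle.
    for sec in sos:
        poles = np.roots([1.0, sec[4], sec[5]])
        if np.any(np.abs(poles) >= 1.0):
            raise ValueError(
                "unstable filter realization for band "
                f"({low_hz}, {high_hz}) Hz at order {order}, fs={rate}"
            )
    return sos


def residual_filter(x: Waveform, band: AcousticBand = AcousticBand()) -> Waveform:
    """Band-pass a signal through the simulated residual-hearing window."""
    sos = _band_sos(band.low_hz, band.high_hz, band.order_per_edge, x.rate)
    if not len(x):
        return x
    return Waveform(signal.sosfilt(sos, x.samples), x.rate)


def band_gain_db(band: AcousticBand, freq_hz, rate: int):
    """Designed-filter magnitude response in dB (analysis/oracle helper)."""
    sos = _band_sos(band.low_hz, band.high_hz, band.order_per_edge, rate)
    _, h = signal.sosfreqz(sos, worN=np.atleast_1d(np.asarray(freq_hz, float)), fs=rate)
    g = 20.0 * np.log10(np.maximum(np.abs(h), 1e-300))
    return float(g[0]) if np.isscalar(freq_hz) else g


def combine_eas(electric: Waveform, acoustic: Waveform) -> Waveform:
    """Sum the electric (vocoded) and acoustic paths within one ear.

    Plain sample-wise addition: relative levels are set upstream by
    each path's own level reference, with no extra EAS weighting.
    """
    require_same_grid(electric, acoustic)
    return Waveform(electric.samples + acoustic.samples, electric.rate)
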