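"""16-channel sine-wave vocoder simulating electric (CI) hearing.

Processing chain, per ear-input signal:

1. first-order high-pass pre-emphasis (cutoff 1200 Hz, 6 dB/oct);
2. Butterworth band-pass analysis filterbank on the allocation's
   Greenwood-spaced band edges (design order 4 per skirt);
3. per-band temporal-envelope extraction by half-wave rectification and
   low-pass filtering at 160 Hz;
4. amplitude modulation of one sine carrier per channel at the
   allocation's carrier frequencies;
5. level restoration: the summed output is rescaled so its long-term
   RMS equals the pre-vocoder input RMS.

Filtering is causal (forward-only) by default, mirroring a real-time
processor; set ``zero_phase=True`` for analysis use.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import List, Optional, Sequence

import numpy as np
from scipy import signal

from .core import Waveform
from .place_map import FrequencyAllocation

__all__ = [
    "VocoderConfig",
    "pre_emphasize",
    "analyze",
    "extract_envelope",
    "synthesize",
    "vocode",
]


@dataclass(frozen=True)
class VocoderConfig:
    allocation: FrequencyAllocation
    preemph_cutoff_hz: float = 1200.0
    analysis_order: int = 4        # Butterworth order per band-pass skirt
    envelope_cutoff_hz: float = 160.0
    envelope_order: int = 4
    carrier_phase_policy: str = "zero"   # "zero" | "random"
    carrier_phase_seed: Optional[int] = None
    zero_phase: bool = False
    level_match: bool = True

    def __post_init__(self) -> None:
        if self.envelope_cutoff_hz <= 0:
            raise ValueError("envelope cutoff must be positive")
        if self.carrier_phase_policy not in ("zero", "random"):
            raise ValueError("carrier_phase_policy must be 'zero' or 'random'")

    def carrier_phases(self) -> np.ndarray:
        n = self.allocation.n_channels
        if self.carrier_phase_policy == "zero":
            return np.zeros(n)
        rng = np.random.default_rng(self.carrier_phase_seed)
        return rng.uniform(0.0, 2 * np.pi, n)


def _apply(sos: np.ndarray, x: np.ndarray, zero_phase: bool) -> np.ndarray:
    return signal.sosfiltfilt(sos, x) if zero_phase else signal.sosfilt(sos, x)


@lru_cache(maxsize=256)
def _butter_sos(order: int, lo: float, hi: Optional[float], btype: str, rate: int):
    wn = lo if hi is None else (lo, hi)
    return signal.butter(order, wn, btype=btype, fs=rate, output="sos")


def pre_emphasize(x: Waveform, cfg: VocoderConfig) -> Waveform:
    """First-order high-pass pre-emphasis (6 dB/octave below cutoff)."""
    if not len(x):
        raise ValueError("empty signal")
    sos = _butter_sos(1, cfg.preemph_cutoff_hz, None, "highpass", x.rate)
    return Waveform(_apply(sos, x.samples, cfg.zero_phase), x.rate)


def analyze(x: Waveform, cfg: VocoderConfig) -> List[Waveform]:
    """Split into the allocation's analysis bands (Butterworth band-passes)."""
    nyq = x.rate / 2.0
    edges = cfg.allocation.input_edges_hz
    if edges[-1] >= nyq:
        raise ValueError(
            f"analysis edge {edges[-1]:.1f} Hz at or above Nyquist ({nyq:.1f} Hz)"
        )
    bands = []
    for ch in range(cfg.allocation.n_channels):
        lo, hi = cfg.allocation.band_edges(ch)
        sos = _butter_sos(cfg.analysis_order, lo, hi, "bandpass", x.rate)
        bands.append(Waveform(_apply(sos, x.samples, cfg.zero_phase), x.rate))
    return bands


def band_gain_db(cfg: VocoderConfig, channel: int, freq_hz, rate: int):
    """Designed analysis-filter magnitude in dB (oracle/analysis helper)."""
    lo, hi = cfg.allocation.band_edges(channel)
    sos = _butter_sos(cfg.analysis_order, lo, hi, "bandpass", rate)
    _, h = signal.sosfreqz(sos, worN=np.atleast_1d(np.asarray(freq_hz, float)), fs=rate)
    g = 20.0 * np.log10(np.maximum(np.abs(h), 1e-300))
    return float(g[0]) if np.isscalar(freq_hz) else g


def extract_envelope(band: Waveform, cfg: VocoderConfig) -> Waveform:
    """Half-wave rectification followed by 160-Hz low-pass filtering."""
    rectified = np.maximum(band.samples, 0.0)
    sos = _butter_sos(cfg.envelope_order, cfg.envelope_cutoff_hz, None, "lowpass", band.rate)
    return Waveform(_apply(sos, rectified, cfg.zero_phase), band.rate)


def synthesize(envelopes: Sequence[Waveform], carriers_hz: Sequence[float],
               rate: int, phases: Optional[Sequence[float]] = None) -> Waveform:
    """Sum of sine carriers amplitude-modulated by the channel envelopes."""
    if len(envelopes) != len(carriers_hz):
        raise ValueError("need exactly one envelope per carrier")
    if not envelopes:
        raise ValueError("no channels to synthesize")
    n = len(envelopes[0])
    if any(len(e) != n for e in envelopes):
        raise ValueError("all envelopes must have the same length")
    nyq = rate / 2.0
    if any(f >= nyq for f in carriers_hz):
        raise ValueError("carrier at or above Nyquist")
    if phases is None:
        phases = np.zeros(len(carriers_hz))
    t = np.arange(n) / rate
    out = np.zeros(n)
    for env, f, phi in zip(envelopes, carriers_hz, phases):
        out += env.samples * np.sin(2 * np.pi * f * t + phi)
    return Waveform(out, rate)


def vocode(x: Waveform, cfg: VocoderConfig) -> Waveform:
    """Full sine-vocoder chain with long-term-RMS level restoration."""
    pre = pre_emphasize(x, cfg)
    bands = analyze(pre, cfg)
    envelopes = [extract_envelope(b, cfg) for b in bands]
    out = synthesize(envelopes, cfg.allocation.carrier_hz, x.rate, cfg.carrier_phases())
    if cfg.level_match:
        in_rms = x.rms()
        out_rms = out.rms()
        # level floor: when the input carries essentially no in-band
        # energy the raw output is vestigial and is left unscaled
        # rather than amplified back up to the input level
        if in_rms > 0 and out_rms > in_rms * 1e-3:
            out = out.scaled(in_rms / out_rms)
    return out
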