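"""WAV file I/O (PCM16 and float32) on top of scipy.io.wavfile."""

from __future__ import annotations

from typing import List, Sequence, Union

import numpy as np
from scipy.io import wavfile

from .core import Waveform

__all__ = ["read_wav", "write_wav"]


def read_wav(path: str) -> List[Waveform]:
    """Read a WAV file; returns one Waveform per channel, floats in ±1."""
    rate, data = wavfile.read(path)
    if data.dtype == np.int16:
        x = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        x = data.astype(np.float64) / 2147483648.0
    elif data.dtype == np.uint8:
        x = (data.astype(np.float64) - 128.0) / 128.0
    else:
        x = data.astype(np.float64)
    if x.ndim == 1:
        return [Waveform(x, rate)]
    return [Waveform(x[:, ch], rate) for ch in range(x.shape[1])]


def write_wav(path: str, channels: Union[Waveform, Sequence[Waveform]],
              dtype: str = "float32") -> None:
    """Write mono or multi-channel audio; dtype 'float32' or 'int16'."""
    if isinstance(channels, Waveform):
        channels = [channels]
    rate = channels[0].rate
    if any(c.rate != rate for c in channels):
        raise ValueError("all channels must share one sample rate")
    n = max(len(c) for c in channels)
    data = np.zeros((n, len(channels)))
    for i, c in enumerate(channels):
        data[: len(c), i] = c.samples
    if len(channels) == 1:
        data = data[:, 0]
    if dtype == "float32":
        wavfile.write(path, rate, data.astype(np.float32))
    elif dtype == "int16":
        peak = np.max(np.abs(data)) if data.size else 0.0
        if peak > 1.0:  # avoid integer wrap-around on hot signals
            data = data / peak
        wavfile.write(path, rate, np.round(data * 32767.0).astype(np.int16))
    else:
        raise ValueError("dtype must be 'float32' or 'int16'")
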