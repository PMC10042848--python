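"""Binaural rendering of target + masker scenes at configured TMRs.

The target always sits at 0° azimuth; the two masker talkers are either
co-located (0°, 0°) or symmetrically separated (+90°, -90°).  The
target-to-masker ratio (TMR) is defined on long-term RMS at the source
(pre-spatialization): maskers are first equalized to a common RMS, then
each is scaled so that 20*log10(RMS_target / RMS_masker) equals the
nominal TMR.  Per-ear effective TMR then emerges from the head model
(head shadow improves the ear contralateral to a masker).

The default renderer is a parametric spherical-head model:

* Woodworth interaural time difference, ITD = a(θ + sin θ)/c, applied
  as a fractional delay to the contralateral ear (head radius a,
  default 8.75 cm; c = 343 m/s);
* a one-pole/one-zero head-shadow filter per ear,
  H(s) = (α s + β)/(s + β) with β = 2c/a and α = 1 + cos(θ_ear),
  where θ_ear is the angle between the source and that ear's axis —
  flat at broadside, a 6 dB/oct high-frequency shadow at the far ear.

An ``HRIRRenderer`` loads user-supplied stereo impulse responses for
exact replication with measured HRTFs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
from scipy import signal

from .core import Waveform, fractional_delay, pad_to, require_same_grid

__all__ = [
    "SceneConfig",
    "SPATIAL_CONFIGS",
    "SphericalHeadRenderer",
    "HRIRRenderer",
    "set_tmr",
    "render_binaural",
    "build_scene",
]

SPEED_OF_SOUND = 343.0  # m/s

#: masker azimuths for the two spatial configurations used throughout
SPATIAL_CONFIGS: Dict[str, Tuple[float, float]] = {
    "colocated": (0.0, 0.0),
    "separated": (90.0, -90.0),
}


@dataclass(frozen=True)
class SceneConfig:
    """Spatial layout and level for one trial's three-talker scene."""

    target_azimuth_deg: float = 0.0
    masker_azimuths_deg: Tuple[float, float] = (0.0, 0.0)
    tmr_db: float = 0.0

    @classmethod
    def from_name(cls, spatial: str, tmr_db: float = 0.0) -> "SceneConfig":
        if spatial not in SPATIAL_CONFIGS:
            raise ValueError(
                f"unknown spatial configuration {spatial!r}; "
                f"valid: {', '.join(SPATIAL_CONFIGS)}"
            )
        return cls(0.0, SPATIAL_CONFIGS[spatial], tmr_db)


def set_tmr(target: Waveform, maskers: Sequence[Waveform], tmr_db: float) -> list:
    """Scale maskers so each sits ``tmr_db`` below the target in long-term RMS.

    Maskers are first equalized to a common RMS, then scaled together;
    the TMR is per masker (so two maskers at 0 dB TMR jointly carry
    ~3 dB more power than the target).
    """
    t_rms = target.rms()
    if t_rms == 0:
        raise ValueError("silent target")
    gain = 10.0 ** (-tmr_db / 20.0)
    out = []
    for m in maskers:
        m_rms = m.rms()
        if m_rms == 0:
            raise ValueError("silent masker")
        out.append(m.scaled(t_rms * gain / m_rms))
    return out


class SphericalHeadRenderer:
    """Parametric binaural renderer (Woodworth ITD + head-shadow filter)."""

    def __init__(self, head_radius_m: float = 0.0875,
                 speed_of_sound: float = SPEED_OF_SOUND) -> None:
        if head_radius_m <= 0:
            raise ValueError("head radius must be positive")
        self.head_radius_m = head_radius_m
        self.speed_of_sound = speed_of_sound

    def itd_s(self, azimuth_deg: float) -> float:
        """Woodworth ITD magnitude for a source at the given azimuth."""
        th = np.deg2rad(abs(azimuth_deg))
        return self.head_radius_m * (th + np.sin(th)) / self.speed_of_sound

    def _shadow(self, x: Waveform, source_az_deg: float, ear_az_deg: float) -> Waveform:
        # angle between source direction and the ear's axis
        th = np.deg2rad(source_az_deg - ear_az_deg)
        alpha = 1.0 + np.cos(th)
        beta = 2.0 * self.speed_of_sound / self.head_radius_m  # rad/s
        b, a = signal.bilinear([alpha, beta], [1.0, beta], fs=x.rate)
        return Waveform(signal.lfilter(b, a, x.samples), x.rate)

    def render(self, source: Waveform, azimuth_deg: float) -> Tuple[Waveform, Waveform]:
        if not -180.0 <= azimuth_deg <= 180.0:
            raise ValueError("azimuth must lie in [-180, 180] degrees")
        left = self._shadow(source, azimuth_deg, -90.0)
        right = self._shadow(source, azimuth_deg, 90.0)
        tau = self.itd_s(azimuth_deg)
        n_out = len(source) + int(np.ceil(tau * source.rate)) + 1
        if azimuth_deg > 0:        # source on the right: delay the left ear
            left = fractional_delay(left, tau)
        elif azimuth_deg < 0:
            right = fractional_delay(right, tau)
        return pad_to(left, n_out), pad_to(right, n_out)


class HRIRRenderer:
    """Render through user-supplied stereo head-related impulse responses.

    Expects a directory of stereo WAV files named ``az<angle>.wav``
    (e.g. ``az0.wav``, ``az90.wav``, ``az-90.wav``), one per supported
    azimuth.
    """

    def __init__(self, directory: str) -> None:
        from .wavio import read_wav  # local import: avoids a cycle

        self._hrirs: Dict[int, Tuple[Waveform, Waveform]] = {}
        for fname in sorted(os.listdir(directory)):
            if not (fname.startswith("az") and fname.endswith(".wav")):
                continue
            angle = int(fname[2:-4])
            channels = read_wav(os.path.join(directory, fname))
            if len(channels) != 2:
                raise ValueError(f"HRIR file {fname} must be stereo")
            self._hrirs[angle] = (channels[0], channels[1])
        if not self._hrirs:
            raise ValueError(f"no az*.wav HRIR files found in {directory}")

    def render(self, source: Waveform, azimuth_deg: float) -> Tuple[Waveform, Waveform]:
        key = int(round(azimuth_deg))
        if key not in self._hrirs:
            raise ValueError(
                f"no HRIR for azimuth {azimuth_deg}; available: {sorted(self._hrirs)}"
            )
        hl, hr = self._hrirs[key]
        if hl.rate != source.rate:
            raise ValueError("HRIR sample rate does not match the source")
        n = len(source) + len(hl) - 1
        left = signal.fftconvolve(source.samples, hl.samples)
        right = signal.fftconvolve(source.samples, hr.samples)
        return Waveform(left, source.rate), Waveform(right, source.rate)


def render_binaural(source: Waveform, azimuth_deg: float,
                    renderer=None) -> Tuple[Waveform, Waveform]:
    """Spatialize a mono source; defaults to the spherical-head model."""
    if renderer is None:
        renderer = SphericalHeadRenderer()
    return renderer.render(source, azimuth_deg)


def build_scene(target: Waveform, maskers: Sequence[Waveform],
                scene: SceneConfig, renderer=None) -> Tuple[Waveform, Waveform]:
    """Render and mix one trial scene into (left, right) ear signals.

    TMR scaling is applied at the source, before spatialization; each
    talker is rendered at its azimuth and the binaural images are
    summed per ear.
    """
    if len(maskers) != len(scene.masker_azimuths_deg):
        raise ValueError("one azimuth per masker required")
    for m in maskers:
        require_same_grid(target, m)
    if renderer is None:
        renderer = SphericalHeadRenderer()
    # silent maskers pass through unscaled (limit case: target alone)
    scaled = [
        m if m.rms() == 0 else set_tmr(target, [m], scene.tmr_db)[0]
        for m in maskers
    ]
    sources = [(target, scene.target_azimuth_deg)] + list(
        zip(scaled, scene.masker_azimuths_deg)
    )
    rendered = [renderer.render(s, az) for s, az in sources]
    n = max(len(l) for l, _ in rendered)
    left = np.zeros(n)
    right = np.zeros(n)
    for l, r in rendered:
        left[: len(l)] += l.samples
        right[: len(r)] += r.samples
    return Waveform(left, target.rate), Waveform(right, target.rate)
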