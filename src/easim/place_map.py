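"""Greenwood place-frequency map, electrode geometry, frequency allocations.

The Greenwood function maps distance ``x`` along the basilar membrane
(measured from the apex, in mm) to the characteristic frequency (CF) of
that cochlear place:

    F(x) = A * (10**(a*x) - k)

With the standard human parameterization (A = 165.4 Hz, a = 0.06 /mm,
k = 0.88, duct length 35 mm) a 16-electrode, 20-mm array inserted 24 mm
from the base spans places 11-31 mm from the apex, i.e. CFs of about
610 Hz (most apical contact) to 11,837 Hz (most basal contact).  Those
two rounded CFs anchor the whole simulated-processor geometry.

Five listening-condition presets are provided:

``bimodal_clinical``
    CI analyzes 200-8000 Hz but carriers sit at the electrode CFs
    (610-11,837 Hz): tonotopically mismatched, like a clinical fit.
``bimodal_adapted``
    Input and output both 200-8000 Hz: a hypothetical complete
    adaptation to the clinical map (matched, full speech band).
``bimodal_match``
    Input and output both 610-11,837 Hz: matched to the electrode
    places, truncating speech below 610 Hz in the CI ear.
``bieas_low`` / ``bieas_high``
    Same electric map as ``bimodal_match`` plus simulated residual
    acoustic hearing in the implanted ear up to 300 / 600 Hz.

All five keep low-frequency acoustic hearing (100-600 Hz) in the
non-implanted ear.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .acoustic_path import AcousticBand

__all__ = [
    "CochlearGeometry",
    "ElectrodeArray",
    "FrequencyAllocation",
    "ListeningCondition",
    "greenwood_frequency",
    "greenwood_place",
    "electrode_places",
    "make_allocation",
    "condition_preset",
    "PRESET_NAMES",
]


@dataclass(frozen=True)
class CochlearGeometry:
    """Human cochlear duct geometry and Greenwood constants."""

    length_mm: float = 35.0
    A: float = 165.4      # Hz
    a: float = 0.06       # per mm
    k: float = 0.88       # dimensionless offset

    def __post_init__(self) -> None:
        if self.length_mm <= 0 or self.A <= 0 or self.a <= 0:
            raise ValueError("length_mm, A and a must all be positive")
        if not 0 <= self.k < 1:
            raise ValueError(f"k must be in [0, 1), got {self.k}")

    @property
    def apex_frequency_hz(self) -> float:
        """CF at the apex (x = 0): the lowest representable frequency."""
        return self.A * (1.0 - self.k)


@dataclass(frozen=True)
class ElectrodeArray:
    """Linear electrode array, placed by insertion depth from the base."""

    n_electrodes: int = 16
    array_length_mm: float = 20.0
    insertion_depth_mm: float = 24.0

    def __post_init__(self) -> None:
        if self.n_electrodes < 1:
            raise ValueError("need at least one electrode")
        if self.array_length_mm < 0 or self.insertion_depth_mm <= 0:
            raise ValueError("array length and insertion depth must be positive")
        if self.array_length_mm > self.insertion_depth_mm:
            raise ValueError(
                "array extends outside the cochlea: "
                f"length {self.array_length_mm} mm > insertion depth "
                f"{self.insertion_depth_mm} mm"
            )


def greenwood_frequency(place_mm_from_apex, geom: CochlearGeometry = CochlearGeometry()):
    """Characteristic frequency (Hz) at a place measured in mm from the apex."""
    x = np.asarray(place_mm_from_apex, dtype=float)
    if np.any(x < 0) or np.any(x > geom.length_mm):
        raise ValueError(
            f"place must lie within [0, {geom.length_mm}] mm from the apex"
        )
    f = geom.A * (10.0 ** (geom.a * x) - geom.k)
    return float(f) if np.isscalar(place_mm_from_apex) else f


def greenwood_place(frequency_hz, geom: CochlearGeometry = CochlearGeometry()):
    """Inverse Greenwood map: place in mm from the apex for a CF in Hz."""
    f = np.asarray(frequency_hz, dtype=float)
    if np.any(f < geom.apex_frequency_hz):
        raise ValueError(
            f"frequency below the apex CF ({geom.apex_frequency_hz:.3f} Hz)"
        )
    x = np.log10(f / geom.A + geom.k) / geom.a
    if np.any(x > geom.length_mm + 1e-9):
        raise ValueError("frequency above the basal-end CF of this cochlea")
    return float(x) if np.isscalar(frequency_hz) else x


def electrode_places(array: ElectrodeArray = ElectrodeArray(),
                     geom: CochlearGeometry = CochlearGeometry()) -> np.ndarray:
    """Electrode places in mm from the apex, apical to basal.

    The most apical contact sits ``insertion_depth_mm`` from the base,
    the remaining contacts are linearly spaced along the array toward
    the base.
    """
    if array.insertion_depth_mm > geom.length_mm:
        raise ValueError("insertion depth exceeds the cochlear duct length")
    apical = geom.length_mm - array.insertion_depth_mm
    basal = apical + array.array_length_mm
    if basal > geom.length_mm:
        raise ValueError("array extends past the base of the cochlea")
    if array.n_electrodes == 1:
        return np.array([apical])
    return np.linspace(apical, basal, array.n_electrodes)


@dataclass(frozen=True)
class FrequencyAllocation:
    """Analysis band edges and sine-carrier frequencies for a processor.

    ``input_edges_hz`` has n_channels + 1 entries; band *i* spans
    ``input_edges_hz[i]``..``input_edges_hz[i+1]``.  Edges and carriers
    are Greenwood CFs of linearly spaced cochlear places, so bands
    partition the input range exactly in place coordinates.
    """

    input_edges_hz: np.ndarray
    carrier_hz: np.ndarray
    input_range_hz: Tuple[float, float]
    output_range_hz: Tuple[float, float]

    def __post_init__(self) -> None:
        edges = np.asarray(self.input_edges_hz, dtype=float)
        carriers = np.asarray(self.carrier_hz, dtype=float)
        if edges.size != carriers.size + 1:
            raise ValueError("need n_channels + 1 edges for n_channels carriers")
        if np.any(np.diff(edges) <= 0) or (carriers.size > 1 and np.any(np.diff(carriers) <= 0)):
            raise ValueError("edges and carriers must be strictly increasing")
        lo, hi = self.input_range_hz
        if abs(edges[0] - lo) > 0.1 or abs(edges[-1] - hi) > 0.1:
            raise ValueError("extreme edges must equal the input range endpoints")
        object.__setattr__(self, "input_edges_hz", edges)
        object.__setattr__(self, "carrier_hz", carriers)

    @property
    def n_channels(self) -> int:
        return self.carrier_hz.size

    def band_edges(self, channel: int) -> Tuple[float, float]:
        return float(self.input_edges_hz[channel]), float(self.input_edges_hz[channel + 1])

    def to_frame(self) -> pd.DataFrame:
        """Tabular export: one row per channel (CSV-friendly)."""
        return pd.DataFrame(
            {
                "channel": np.arange(1, self.n_channels + 1),
                "low_hz": self.input_edges_hz[:-1],
                "high_hz": self.input_edges_hz[1:],
                "carrier_hz": self.carrier_hz,
            }
        )


def make_allocation(input_range_hz: Tuple[float, float],
                    output_range_hz: Tuple[float, float],
                    n_channels: int = 16,
                    geom: CochlearGeometry = CochlearGeometry()) -> FrequencyAllocation:
    """Build a Greenwood-spaced analysis/carrier allocation.

    Analysis-band edges are the CFs of ``n_channels + 1`` linearly
    spaced places spanning the place interval of the input range;
    carriers are the CFs of ``n_channels`` linearly spaced places
    spanning the place interval of the output range (so with 16
    channels and the electrode-matched output range the carriers fall
    exactly on the electrode CFs).
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    for name, (lo, hi) in (("input", tuple(input_range_hz)), ("output", tuple(output_range_hz))):
        if not lo < hi:
            raise ValueError(f"{name} range is inverted or degenerate: ({lo}, {hi})")
    in_places = np.linspace(
        greenwood_place(input_range_hz[0], geom),
        greenwood_place(input_range_hz[1], geom),
        n_channels + 1,
    )
    if n_channels == 1:
        out_places = np.array([
            0.5 * (greenwood_place(output_range_hz[0], geom)
                   + greenwood_place(output_range_hz[1], geom))
        ])
    else:
        out_places = np.linspace(
            greenwood_place(output_range_hz[0], geom),
            greenwood_place(output_range_hz[1], geom),
            n_channels,
        )
    return FrequencyAllocation(
        input_edges_hz=greenwood_frequency(in_places, geom),
        carrier_hz=greenwood_frequency(out_places, geom),
        input_range_hz=(float(input_range_hz[0]), float(input_range_hz[1])),
        output_range_hz=(float(output_range_hz[0]), float(output_range_hz[1])),
    )


@dataclass(frozen=True)
class ListeningCondition:
    """Per-ear processing recipe for one simulated listening condition.

    The non-implanted (contralateral) ear always receives band-limited
    acoustic hearing; the implanted ear receives the vocoder with the
    condition's frequency allocation and, for the BiEAS conditions,
    additional low-frequency acoustic hearing.
    """

    name: str
    ci_allocation: FrequencyAllocation
    contra_acoustic: AcousticBand
    ci_ear_acoustic: Optional[AcousticBand] = None


PRESET_NAMES = (
    "bimodal_clinical",
    "bimodal_adapted",
    "bimodal_match",
    "bieas_low",
    "bieas_high",
)

_SPEECH_RANGE = (200.0, 8000.0)
_CONTRA_BAND = AcousticBand(100.0, 600.0)


def condition_preset(name: str,
                     geom: CochlearGeometry = CochlearGeometry(),
                     array: ElectrodeArray = ElectrodeArray()) -> ListeningCondition:
    """Return the full per-ear recipe for one of the five named conditions."""
    if name not in PRESET_NAMES:
        raise ValueError(
            f"unknown condition {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        )
    places = electrode_places(array, geom)
    electrode_range = (
        float(greenwood_frequency(places[0], geom)),
        float(greenwood_frequency(places[-1], geom)),
    )
    n = array.n_electrodes
    if name == "bimodal_clinical":
        alloc = make_allocation(_SPEECH_RANGE, electrode_range, n, geom)
        ci_acoustic = None
    elif name == "bimodal_adapted":
        alloc = make_allocation(_SPEECH_RANGE, _SPEECH_RANGE, n, geom)
        ci_acoustic = None
    elif name == "bimodal_match":
        alloc = make_allocation(electrode_range, electrode_range, n, geom)
        ci_acoustic = None
    elif name == "bieas_low":
        alloc = make_allocation(electrode_range, electrode_range, n, geom)
        ci_acoustic = AcousticBand(100.0, 300.0)
    else:  # bieas_high
        alloc = make_allocation(electrode_range, electrode_range, n, geom)
        ci_acoustic = AcousticBand(100.0, 600.0)
    return ListeningCondition(
        name=name,
        ci_allocation=alloc,
        contra_acoustic=_CONTRA_BAND,
        ci_ear_acoustic=ci_acoustic,
    )
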