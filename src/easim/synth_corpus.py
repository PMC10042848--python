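"""Synthetic closed-set matrix-sentence corpus.

Emulates a sung/matrix speech test: 5 word categories (Name, Verb,
Number, Color, Object) x 10 monosyllabic words x 3 male talkers.  The
target talker has a nominal mean F0 of 106 Hz; the two masker talkers
97 Hz and 128 Hz.  Target sentences always begin with the fixed Name
cue word (index 0, the "John" token); masker sentences draw, per
category, words different from the target and from each other.

Words are parametric source-filter synthesis, not recordings: a voiced
harmonic source at the talker's F0 (with a mild per-token contour),
shaped by a word-specific 4-formant spectral envelope spanning
100-8000 Hz, with a raised-cosine onset/offset.  The formant signature
depends only on (category, word index), so the "same word" is
recognizably shared across talkers, while F0, duration and phase detail
vary per token.  Word durations are drawn uniformly from 0.35-0.50 s.

Masker sentences are duration-normalized to the target sentence by
waveform-similarity overlap-add (WSOLA) time-scale modification, which
changes duration without affecting pitch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import DEFAULT_RATE, REFERENCE_RMS, Waveform

__all__ = [
    "CATEGORIES",
    "TALKERS",
    "TALKER_F0_HZ",
    "CUE_WORD_INDEX",
    "WordToken",
    "Sentence",
    "Trial",
    "Corpus",
    "synth_word",
    "normalize_duration",
    "time_stretch",
    "estimate_f0",
]

CATEGORIES = ("name", "verb", "number", "color", "object")
TALKERS = ("target", "maskerA", "maskerB")
TALKER_F0_HZ = {"target": 106.0, "maskerA": 97.0, "maskerB": 128.0}
N_WORDS = 10
#: Name index 0 is the fixed target-sentence cue word ("John" token)
CUE_WORD_INDEX = 0

DURATION_RANGE_S = (0.35, 0.50)

# namespace keys for deterministic, independent random streams
_WORD_IDENTITY_KEY = 271828   # word spectral signatures (seed-independent)
_TOKEN_KEY = 314159           # per-token realization (seed-dependent)


@dataclass(frozen=True)
class WordToken:
    category: str
    index: int
    talker: str
    f0_hz: float
    duration_s: float
    waveform: Waveform
    formants_hz: Tuple[float, ...]

    @property
    def spectral_id(self) -> Tuple[float, ...]:
        """Word-identity signature: the formant pattern."""
        return self.formants_hz


@dataclass(frozen=True)
class Sentence:
    """Five concatenated word tokens (one per category, fixed order)."""

    words: Tuple[WordToken, ...]
    talker: str
    waveform: Waveform
    word_offsets: np.ndarray  # start sample of each word in the waveform

    @property
    def word_indices(self) -> Tuple[int, ...]:
        return tuple(w.index for w in self.words)

    def word_bounds(self, category: str) -> Tuple[int, int]:
        """(start, end) sample of one category's word within the sentence."""
        i = CATEGORIES.index(category)
        start = int(self.word_offsets[i])
        end = int(self.word_offsets[i + 1]) if i + 1 < len(self.word_offsets) \
            else len(self.waveform)
        return start, end


@dataclass(frozen=True)
class Trial:
    target: Sentence
    maskers: Tuple[Sentence, Sentence]


def _word_params(category: str, index: int):
    """Deterministic word-identity signature.

    Each word of the closed set gets a fixed 4-formant spectral
    envelope and a fixed coarse temporal energy contour (monosyllables
    differ in their consonant-vowel dynamics), shared across talkers
    and corpus seeds so the "same word" is recognizable everywhere.
    """
    cat_idx = CATEGORIES.index(category)
    rng = np.random.default_rng(
        np.random.SeedSequence([_WORD_IDENTITY_KEY, cat_idx, index])
    )
    formants = np.array([
        rng.uniform(280, 850),
        rng.uniform(950, 2300),
        rng.uniform(2450, 3400),
        rng.uniform(3500, 4800),
    ])
    bandwidths = rng.uniform(60, 130, size=4)
    # coarse energy contour: control points over the word's duration
    contour = rng.uniform(0.25, 1.0, size=5)
    contour[int(rng.integers(1, 4))] = 1.0  # every word peaks somewhere inside
    return formants, bandwidths, contour


def _word_formants(category: str, index: int) -> Tuple[np.ndarray, np.ndarray]:
    formants, bandwidths, _ = _word_params(category, index)
    return formants, bandwidths


def _spectral_envelope(freq_hz: np.ndarray, formants: np.ndarray,
                       bandwidths: np.ndarray) -> np.ndarray:
    """Formant-sum amplitude envelope with a gentle high-frequency tilt."""
    amp = np.zeros_like(freq_hz, dtype=float)
    for f, bw in zip(formants, bandwidths):
        amp += 1.0 / (1.0 + ((freq_hz - f) / bw) ** 2)
    amp += 0.03  # broadband floor keeps energy out to 8 kHz
    tilt = 1.0 / np.sqrt(1.0 + (freq_hz / 3500.0) ** 2)
    return amp * tilt


def synth_word(category: str, index: int, talker: str, seed: int = 0,
               rate: int = DEFAULT_RATE) -> WordToken:
    """Synthesize one word token; bit-identical for identical arguments."""
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    if not 0 <= index < N_WORDS:
        raise ValueError(f"word index must be in [0, {N_WORDS}), got {index}")
    if talker not in TALKERS:
        raise ValueError(f"unknown talker {talker!r}")

    cat_idx = CATEGORIES.index(category)
    talker_idx = TALKERS.index(talker)
    rng = np.random.default_rng(
        np.random.SeedSequence([_TOKEN_KEY, seed, cat_idx, index, talker_idx])
    )

    duration_s = rng.uniform(*DURATION_RANGE_S)
    n = int(round(duration_s * rate))
    nominal = TALKER_F0_HZ[talker]
    f0_mean = nominal * (1.0 + rng.uniform(-0.02, 0.02))
    glide = rng.uniform(-0.02, 0.02)  # fractional F0 change across the token

    t = np.arange(n) / rate
    f0_t = f0_mean * (1.0 + glide * (t / duration_s - 0.5))
    phase = 2.0 * np.pi * np.cumsum(f0_t) / rate

    formants, bandwidths, contour = _word_params(category, index)
    n_harm = int(min(8000.0, 0.45 * rate) // (f0_mean * (1 + abs(glide) / 2)))
    k = np.arange(1, n_harm + 1)
    amps = _spectral_envelope(k * f0_mean, formants, bandwidths)
    phis = rng.uniform(0.0, 2.0 * np.pi, n_harm)

    x = np.sin(phase[:, None] * k[None, :] + phis[None, :]) @ amps

    # word-identity energy contour (smooth through the control points)
    from scipy.interpolate import PchipInterpolator

    knots = np.linspace(0.0, duration_s, contour.size)
    env = PchipInterpolator(knots, contour)(t)
    # raised-cosine onset/offset so tokens don't click at the joins
    attack = int(0.030 * rate)
    release = int(0.050 * rate)
    env[:attack] *= 0.5 * (1 - np.cos(np.pi * np.arange(attack) / attack))
    env[n - release:] *= 0.5 * (1 + np.cos(np.pi * np.arange(release) / release))
    x *= env

    wave = Waveform(x, rate).with_rms(REFERENCE_RMS)
    return WordToken(category, index, talker, f0_mean, duration_s, wave,
                     tuple(formants))


class Corpus:
    """The full 5x10x3 token inventory for one corpus seed."""

    def __init__(self, seed: int = 0, rate: int = DEFAULT_RATE) -> None:
        self.seed = seed
        self.rate = rate
        self._tokens: Dict[Tuple[str, int, str], WordToken] = {}
        for category in CATEGORIES:
            for index in range(N_WORDS):
                for talker in TALKERS:
                    self._tokens[(category, index, talker)] = synth_word(
                        category, index, talker, seed=seed, rate=rate
                    )

    def token(self, category: str, index: int, talker: str) -> WordToken:
        return self._tokens[(category, index, talker)]

    def tokens(self, talker: Optional[str] = None) -> List[WordToken]:
        if talker is None:
            return list(self._tokens.values())
        return [tok for key, tok in self._tokens.items() if key[2] == talker]

    def sentence(self, talker: str, indices: Sequence[int]) -> Sentence:
        """Concatenate one word per category into a sentence waveform."""
        if len(indices) != len(CATEGORIES):
            raise ValueError("need one word index per category")
        words = tuple(
            self.token(cat, idx, talker) for cat, idx in zip(CATEGORIES, indices)
        )
        offsets = np.cumsum([0] + [len(w.waveform) for w in words[:-1]])
        samples = np.concatenate([w.waveform.samples for w in words])
        return Sentence(words, talker, Waveform(samples, self.rate), offsets)

    def sample_trial(self, rng: np.random.Generator) -> Trial:
        """Draw one target + two masker sentences with disjoint words.

        The target Name is always the cue word; in every category the
        three sentences use three distinct word indices.
        """
        target_idx: List[int] = []
        masker_a_idx: List[int] = []
        masker_b_idx: List[int] = []
        for category in CATEGORIES:
            if category == "name":
                t = CUE_WORD_INDEX
                others = rng.choice(
                    [i for i in range(N_WORDS) if i != t], size=2, replace=False
                )
                a, b = int(others[0]), int(others[1])
            else:
                picks = rng.choice(N_WORDS, size=3, replace=False)
                t, a, b = (int(p) for p in picks)
            target_idx.append(t)
            masker_a_idx.append(a)
            masker_b_idx.append(b)
        return Trial(
            target=self.sentence("target", target_idx),
            maskers=(
                self.sentence("maskerA", masker_a_idx),
                self.sentence("maskerB", masker_b_idx),
            ),
        )

    def manifest(self) -> pd.DataFrame:
        rows = [
            {
                "category": tok.category,
                "index": tok.index,
                "talker": tok.talker,
                "f0_hz": tok.f0_hz,
                "duration_s": tok.duration_s,
                "file": f"{tok.category}{tok.index:02d}_{tok.talker}.wav",
            }
            for tok in self._tokens.values()
        ]
        return pd.DataFrame(rows)

    def save(self, directory: str) -> None:
        """Write all 150 tokens as WAV files plus a manifest CSV."""
        import os

        from .wavio import write_wav

        os.makedirs(directory, exist_ok=True)
        manifest = self.manifest()
        for _, row in manifest.iterrows():
            tok = self.token(row["category"], int(row["index"]), row["talker"])
            write_wav(os.path.join(directory, row["file"]), tok.waveform)
        manifest.to_csv(os.path.join(directory, "manifest.csv"), index=False)


def time_stretch(x: np.ndarray, target_len: int, rate: int,
                 frame_s: float = 0.050, search_s: float = 0.008) -> np.ndarray:
    """WSOLA time-scale modification to an exact output length.

    Overlap-adds Hann-windowed input frames at a fixed synthesis hop,
    choosing each frame's source position within a small search window
    to maximize waveform similarity with the natural continuation of
    the previous frame — duration changes, pitch does not.
    """
    x = np.asarray(x, dtype=float)
    n_in = x.size
    if target_len < 1 or n_in < 1:
        raise ValueError("empty input or target")
    if n_in == target_len:
        return x.copy()
    ratio = n_in / target_len
    if not 0.5 <= ratio <= 2.0:
        raise ValueError(f"stretch ratio {1/ratio:.2f} outside [0.5, 2]")

    frame = int(round(frame_s * rate))
    frame += frame % 2
    if n_in <= frame or target_len <= frame:
        # too short for overlap-add: fall back to simple resampling of
        # the envelope positions (only reachable for sub-frame inputs)
        idx = np.minimum((np.arange(target_len) * ratio).astype(int), n_in - 1)
        return x[idx]
    hop = frame // 2
    search = int(round(search_s * rate))
    window = np.hanning(frame + 1)[:frame]

    out = np.zeros(target_len + frame)
    wsum = np.zeros(target_len + frame)
    prev_start = 0
    denom = max(target_len - frame, 1)
    for p in range(0, target_len, hop):
        q = int(round(p * (n_in - frame) / denom))
        if p == 0:
            s = q
        else:
            ideal = min(max(prev_start + hop, 0), n_in - frame)
            lo = max(0, q - search)
            hi = min(n_in - frame, q + search)
            if hi <= lo:
                s = min(max(q, 0), n_in - frame)
            else:
                ref = x[ideal:ideal + frame]
                corr = np.correlate(x[lo:hi + frame], ref, mode="valid")
                s = lo + int(np.argmax(corr))
        out[p:p + frame] += x[s:s + frame] * window
        wsum[p:p + frame] += window
        prev_start = s
    safe = wsum > 1e-3
    out[safe] /= wsum[safe]
    return out[:target_len]


def normalize_duration(masker: Sentence, target: Sentence) -> Sentence:
    """Time-scale a masker sentence to the target's exact sample count."""
    if masker.waveform.rate != target.waveform.rate:
        raise ValueError("sentences must share a sample rate")
    n_target = len(target.waveform)
    n_masker = len(masker.waveform)
    if n_masker == n_target:
        return masker
    stretched = time_stretch(masker.waveform.samples, n_target,
                             masker.waveform.rate)
    scale = n_target / n_masker
    return Sentence(
        words=masker.words,
        talker=masker.talker,
        waveform=Waveform(stretched, masker.waveform.rate),
        word_offsets=np.round(masker.word_offsets * scale).astype(int),
    )


def estimate_f0(x: Waveform, fmin_hz: float = 60.0, fmax_hz: float = 400.0,
                frame_s: float = 0.040, voicing_threshold: float = 0.3) -> float:
    """Autocorrelation F0 estimate: median over voiced frames, in Hz.

    Per frame, the normalized autocorrelation peak within the candidate
    lag range is refined by parabolic interpolation; frames whose peak
    falls below ``voicing_threshold`` are treated as unvoiced and
    dropped.  Returns NaN if no frame is voiced.
    """
    rate = x.rate
    frame = int(frame_s * rate)
    hop = frame // 2
    lag_lo = int(rate / fmax_hz)
    lag_hi = int(np.ceil(rate / fmin_hz))
    if frame <= lag_hi or len(x) < frame:
        raise ValueError("signal too short for the requested F0 range")
    estimates = []
    for start in range(0, len(x) - frame + 1, hop):
        seg = x.samples[start:start + frame]
        seg = seg - seg.mean()
        r0 = float(seg @ seg)
        if r0 <= 0:
            continue
        ac = np.correlate(seg, seg, mode="full")[frame - 1:]
        ac = ac / r0
        window = ac[lag_lo:lag_hi + 1]
        peak = int(np.argmax(window))
        lag = lag_lo + peak
        if ac[lag] < voicing_threshold:
            continue
        if 0 < lag < len(ac) - 1:  # parabolic refinement
            y0, y1, y2 = ac[lag - 1], ac[lag], ac[lag + 1]
            d = y0 - 2 * y1 + y2
            if d != 0:
                lag = lag + 0.5 * (y0 - y2) / d
        estimates.append(rate / lag)
    if not estimates:
        return float("nan")
    return float(np.median(estimates))
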