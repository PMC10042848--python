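"""Simulated listeners standing in for the human participants.

Two observers are provided.  :class:`PsychometricOracle` is an
audio-free test double with a known logistic psychometric function for
the both-keywords-correct event — the ground truth against which the
adaptive staircase is validated.  :class:`TemplateObserver` actually
listens: it matches the condition-processed mixture against internal
templates of cleanly processed word tokens, yielding a monotone (but
not human-calibrated) psychometric function for every listening
condition.  Neither claims to reproduce human speech-reception
thresholds; they exist so the full pipeline can be exercised and its
qualitative behavior verified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal
from scipy.special import expit

from .core import Waveform
from .place_map import ListeningCondition
from .spatial_scene import SceneConfig, SphericalHeadRenderer
from .synth_corpus import N_WORDS, Corpus, Sentence

__all__ = [
    "PsychometricOracle",
    "TemplateObserver",
    "psychometric_curve",
    "fit_logistic_threshold",
]

#: the response grid offers 10 alternatives per keyword
KEYWORD_CATEGORIES = ("number", "color")
CHANCE_PER_KEYWORD = 1.0 / N_WORDS


@dataclass(frozen=True)
class PsychometricOracle:
    """Known logistic both-keywords psychometric function.

    P(both correct | TMR) = g + (1 - g - lapse) * expit(slope * (TMR - threshold))

    with guess floor g = (per-keyword chance)^2 = 0.01 for the 10x10
    closed-set response grid.  ``threshold_db`` is the TMR at the
    midpoint of the function's own range.
    """

    threshold_db: float = 5.0
    slope_per_db: float = 1.0
    guess_rate: float = CHANCE_PER_KEYWORD
    lapse_rate: float = 0.0
    requires_audio: bool = field(default=False, init=False)

    @property
    def guess_both(self) -> float:
        return self.guess_rate**2

    def prob_both_correct(self, tmr_db) -> np.ndarray:
        g = self.guess_both
        p = g + (1.0 - g - self.lapse_rate) * expit(
            self.slope_per_db * (np.asarray(tmr_db, dtype=float) - self.threshold_db)
        )
        return float(p) if np.isscalar(tmr_db) else p

    def respond(self, tmr_db: float, rng: np.random.Generator) -> bool:
        """Draw one both-keywords-correct outcome at the given TMR."""
        return bool(rng.random() < self.prob_both_correct(tmr_db))


def _erb_hz(f_hz: np.ndarray) -> np.ndarray:
    """Equivalent rectangular bandwidth of the auditory filter at f."""
    return 24.7 * (4.37 * f_hz / 1000.0 + 1.0)


def _erb_space(fmin: float, fmax: float, n: int) -> np.ndarray:
    """Center frequencies uniformly spaced on the ERB-number scale."""
    def erb_number(f):
        return 21.4 * np.log10(4.37 * f / 1000.0 + 1.0)

    def inv_erb_number(e):
        return (10.0 ** (e / 21.4) - 1.0) * 1000.0 / 4.37

    return inv_erb_number(np.linspace(erb_number(fmin), erb_number(fmax), n))


class TemplateObserver:
    """Template-matching listener over an auditory-envelope front end.

    Front end: a 30-channel ERB-spaced band-pass filterbank
    (gammatone-like selectivity, realized as 4th-order Butterworth
    band-passes one ERB wide about each center), half-wave
    rectification, 50-Hz envelope smoothing, downsampling to a frame
    rate, and log compression.  Templates are the front-end images of
    each candidate Number/Color token of the target talker, rendered at
    0 degrees and processed through the observer's listening condition.
    Identification picks, per keyword, the template with the highest
    normalized correlation against the corresponding segment of the
    trial mixture, summing similarity across the two ears.
    """

    requires_audio = True

    def __init__(self, corpus: Corpus, condition: ListeningCondition,
                 renderer=None, n_channels: int = 30,
                 fmin_hz: float = 80.0, fmax_hz: float = 8000.0,
                 frame_rate_hz: float = 200.0,
                 env_cutoff_hz: float = 50.0) -> None:
        self.corpus = corpus
        self.condition = condition
        self.renderer = renderer if renderer is not None else SphericalHeadRenderer()
        self.rate = corpus.rate
        self.frame_step = max(1, int(round(corpus.rate / frame_rate_hz)))
        nyq = corpus.rate / 2.0
        cfs = _erb_space(fmin_hz, min(fmax_hz, 0.9 * nyq), n_channels)
        self._bank = []
        for cf in cfs:
            bw = _erb_hz(np.array(cf))
            lo = max(cf - bw, 20.0)
            hi = min(cf + bw, 0.95 * nyq)
            self._bank.append(
                signal.butter(2, (lo, hi), btype="bandpass", fs=corpus.rate,
                              output="sos")
            )
        self._env_sos = signal.butter(2, env_cutoff_hz, btype="lowpass",
                                      fs=corpus.rate, output="sos")
        self._templates = self._build_templates()

    # -- front end ---------------------------------------------------------

    def _frontend(self, x: np.ndarray) -> np.ndarray:
        """(n_channels, n_frames) log-compressed envelope image."""
        feats = []
        for sos in self._bank:
            band = signal.sosfilt(sos, x)
            env = signal.sosfilt(self._env_sos, np.maximum(band, 0.0))
            feats.append(env[:: self.frame_step])
        feats = np.asarray(feats)
        floor = 1e-6
        return np.log10(np.maximum(feats, floor) / floor)

    # -- templates ---------------------------------------------------------

    def _build_templates(self) -> Dict[str, list]:
        from .pipeline import process_condition  # deferred: avoids a cycle

        templates: Dict[str, list] = {}
        for category in KEYWORD_CATEGORIES:
            per_word = []
            for index in range(N_WORDS):
                token = self.corpus.token(category, index, "target")
                left, right = self.renderer.render(token.waveform, 0.0)
                pl, pr = process_condition(left, right, self.condition)
                per_word.append(
                    (self._frontend(pl.samples), self._frontend(pr.samples))
                )
            templates[category] = per_word
        return templates

    # -- decision ----------------------------------------------------------

    @staticmethod
    def _similarity(segment: np.ndarray, template: np.ndarray) -> float:
        """Best normalized correlation over candidate time alignments.

        The shorter envelope matrix slides along the longer one and the
        maximum patch-wise normalized cross-correlation is returned, so
        word duration and internal timing both inform the match.
        """
        if segment.shape[1] < template.shape[1]:
            segment, template = template, segment
        k = template.shape[1]
        b = template - template.mean()
        b_norm = np.linalg.norm(b)
        if b_norm == 0:
            return 0.0
        best = -np.inf
        for off in range(segment.shape[1] - k + 1):
            a = segment[:, off:off + k]
            a = a - a.mean()
            denom = np.linalg.norm(a) * b_norm
            score = 0.0 if denom == 0 else float(np.sum(a * b) / denom)
            best = max(best, score)
        return best

    #: seconds of context added around a keyword segment before matching
    ALIGN_MARGIN_S = 0.04

    def identify(self, mix: Tuple[Waveform, Waveform], target: Sentence,
                 alternatives: Optional[Dict[str, Sequence[int]]] = None
                 ) -> Dict[str, int]:
        """Choose one of the 10 alternatives for each keyword category."""
        if not self._templates:
            raise RuntimeError("templates not built")
        left, right = mix
        margin = int(self.ALIGN_MARGIN_S * self.rate)
        choices: Dict[str, int] = {}
        for category in KEYWORD_CATEGORIES:
            start, end = target.word_bounds(category)
            lo = max(0, start - margin)
            hi = min(len(left), end + margin)
            seg_l = self._frontend(left.samples[lo:hi])
            seg_r = self._frontend(right.samples[lo:hi])
            candidates = (alternatives or {}).get(category, range(N_WORDS))
            best_idx, best_score = -1, -np.inf
            for index in candidates:
                tpl_l, tpl_r = self._templates[category][index]
                score = self._similarity(seg_l, tpl_l) + self._similarity(seg_r, tpl_r)
                if score > best_score:
                    best_idx, best_score = index, score
            choices[category] = best_idx
        return choices


def psychometric_curve(observer, condition: ListeningCondition,
                       spatial: str, corpus: Optional[Corpus],
                       tmr_grid_db: Sequence[float], n_per_point: int,
                       seed: int, renderer=None,
                       ci_alpha: float = 0.05) -> pd.DataFrame:
    """Empirical both-keywords-correct proportion per TMR, with binomial CIs."""
    from statsmodels.stats.proportion import proportion_confint

    from .pipeline import run_trial

    if n_per_point < 1:
        raise ValueError("n_per_point must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 424242]))
    rows = []
    for tmr in tmr_grid_db:
        scene = SceneConfig.from_name(spatial, tmr_db=tmr)
        k = sum(
            run_trial(observer, corpus, condition, scene, rng, renderer)
            for _ in range(n_per_point)
        )
        lo, hi = proportion_confint(k, n_per_point, alpha=ci_alpha, method="wilson")
        rows.append(
            {"tmr_db": tmr, "n": n_per_point, "n_correct": int(k),
             "p_correct": k / n_per_point, "ci_low": lo, "ci_high": hi}
        )
    return pd.DataFrame(rows)


def fit_logistic_threshold(tmr_db: Sequence[float], p_correct: Sequence[float],
                           guess: float = CHANCE_PER_KEYWORD**2,
                           lapse: float = 0.0) -> Tuple[float, float]:
    """Least-squares logistic fit; returns (threshold_db, slope_per_db)."""
    from scipy.optimize import curve_fit

    x = np.asarray(tmr_db, float)
    y = np.asarray(p_correct, float)

    def model(t, threshold, slope):
        return guess + (1.0 - guess - lapse) * expit(slope * (t - threshold))

    p0 = (float(np.median(x)), 1.0)
    popt, _ = curve_fit(model, x, y, p0=p0, maxfev=10_000)
    return float(popt[0]), float(popt[1])
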