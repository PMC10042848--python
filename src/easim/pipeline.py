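"""End-to-end trial rendering: corpus -> scene -> per-ear processing.

One trial proceeds exactly as in the simulated experiment: sample a
target and two masker sentences, duration-normalize the maskers to the
target, set the nominal TMR on long-term RMS, spatialize each talker,
mix per ear, then apply the listening condition — the left
(non-implanted) ear gets the residual-hearing band-pass, the right
(implanted) ear gets the sine vocoder and, for BiEAS conditions, an
additional residual-hearing band summed with the electric signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .acoustic_path import combine_eas, residual_filter
from .core import Waveform
from .place_map import ListeningCondition
from .spatial_scene import SceneConfig, build_scene
from .synth_corpus import CATEGORIES, Corpus, Sentence, Trial, normalize_duration
from .vocoder import VocoderConfig, vocode

__all__ = ["RenderedTrial", "render_trial", "process_condition", "run_trial"]


@dataclass(frozen=True)
class RenderedTrial:
    """A spatialized (but not yet condition-processed) trial mixture."""

    left: Waveform
    right: Waveform
    target: Sentence
    tmr_db: float


def render_trial(trial: Trial, scene: SceneConfig,
                 renderer=None) -> RenderedTrial:
    """Duration-normalize, level, spatialize and mix one trial."""
    maskers = [normalize_duration(m, trial.target) for m in trial.maskers]
    left, right = build_scene(
        trial.target.waveform, [m.waveform for m in maskers], scene, renderer
    )
    return RenderedTrial(left, right, trial.target, scene.tmr_db)


def process_condition(left: Waveform, right: Waveform,
                      condition: ListeningCondition,
                      vocoder_config: Optional[VocoderConfig] = None
                      ) -> Tuple[Waveform, Waveform]:
    """Apply a listening condition's per-ear processing to an ear pair."""
    if vocoder_config is None:
        vocoder_config = VocoderConfig(allocation=condition.ci_allocation)
    elif vocoder_config.allocation is not condition.ci_allocation:
        raise ValueError("vocoder config allocation differs from the condition's")
    left_out = residual_filter(left, condition.contra_acoustic)
    electric = vocode(right, vocoder_config)
    if condition.ci_ear_acoustic is not None:
        acoustic = residual_filter(right, condition.ci_ear_acoustic)
        right_out = combine_eas(electric, acoustic)
    else:
        right_out = electric
    return left_out, right_out


def run_trial(observer, corpus: Corpus, condition: ListeningCondition,
              scene: SceneConfig, rng: np.random.Generator,
              renderer=None) -> bool:
    """Run one full trial and return the both-keywords-correct outcome.

    Audio-free observers (psychometric oracles) are probed directly at
    the scene's TMR; listening observers get the condition-processed
    binaural mixture.
    """
    if not getattr(observer, "requires_audio", True):
        return bool(observer.respond(scene.tmr_db, rng))
    trial = corpus.sample_trial(rng)
    rendered = render_trial(trial, scene, renderer)
    left, right = process_condition(rendered.left, rendered.right, condition)
    choices = observer.identify((left, right), rendered.target)
    truth = {
        cat: rendered.target.words[CATEGORIES.index(cat)].index
        for cat in ("number", "color")
    }
    return all(choices[cat] == truth[cat] for cat in ("number", "color"))
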