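"""Adaptive 1-up/1-down TMR tracking and experiment orchestration.

The speech-reception threshold (SRT) for a condition is measured with a
1-up/1-down staircase on the trial TMR: a both-keywords-correct
response lowers the TMR by the current step, anything else raises it.
The step is 4 dB until the second reversal, then 2 dB; the track stops
after a total number of reversals (default 10) or a trial cap, and the
SRT is the mean TMR at the last six reversals — the level converging on
50% correct identification of both keywords.  The default termination
leaves two settling reversals between the step-size change and the six
averaged reversals, so the averaged window is free of the transient
from the supra-threshold starting level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .core import REFERENCE_RMS
from .place_map import ListeningCondition, condition_preset
from .spatial_scene import SPATIAL_CONFIGS, SceneConfig
from .synth_corpus import Corpus

__all__ = [
    "StaircaseConfig",
    "StaircaseTrace",
    "run_staircase",
    "run_track",
    "run_experiment",
]


@dataclass(frozen=True)
class StaircaseConfig:
    initial_tmr_db: float = 10.0
    initial_step_db: float = 4.0
    final_step_db: float = 2.0
    reversals_for_step_change: int = 2
    reversals_to_average: int = 6
    total_reversals: int = 10
    max_trials: int = 60
    #: digital RMS standing in for the experiment's fixed 65 dBA target level
    target_level_reference: float = REFERENCE_RMS

    def __post_init__(self) -> None:
        if self.total_reversals < self.reversals_for_step_change + self.reversals_to_average:
            raise ValueError(
                "total_reversals must cover the large-step phase plus the "
                "reversals being averaged"
            )
        if self.initial_step_db <= 0 or self.final_step_db <= 0:
            raise ValueError("step sizes must be positive")
        if self.max_trials < 1:
            raise ValueError("max_trials must be >= 1")


@dataclass(frozen=True)
class StaircaseTrace:
    """Complete record of one adaptive track."""

    tmr_db: np.ndarray          # TMR presented on each trial
    correct: np.ndarray         # both-keywords-correct flag per trial
    reversal: np.ndarray        # True where the step direction reversed
    step_db: np.ndarray         # step size applied after each trial
    srt_db: float
    n_trials: int
    converged: bool

    @property
    def reversal_tmrs_db(self) -> np.ndarray:
        return self.tmr_db[self.reversal]


def run_staircase(respond: Callable[[float], bool],
                  cfg: StaircaseConfig = StaircaseConfig()) -> StaircaseTrace:
    """Drive a 1-up/1-down track against any trial-response callable."""
    tmrs: List[float] = []
    corrects: List[bool] = []
    reversals: List[bool] = []
    steps: List[float] = []

    tmr = cfg.initial_tmr_db
    prev_direction = 0  # -1 down, +1 up
    n_reversals = 0

    for _ in range(cfg.max_trials):
        correct = bool(respond(tmr))
        direction = -1 if correct else +1
        is_reversal = prev_direction != 0 and direction != prev_direction
        if is_reversal:
            n_reversals += 1
        step = (cfg.initial_step_db
                if n_reversals < cfg.reversals_for_step_change
                else cfg.final_step_db)
        tmrs.append(tmr)
        corrects.append(correct)
        reversals.append(is_reversal)
        steps.append(step)
        if n_reversals >= cfg.total_reversals:
            break
        tmr += direction * step
        prev_direction = direction

    reversal_arr = np.asarray(reversals)
    reversal_tmrs = np.asarray(tmrs)[reversal_arr]
    converged = n_reversals >= cfg.total_reversals
    if reversal_tmrs.size >= cfg.reversals_to_average:
        srt = float(np.mean(reversal_tmrs[-cfg.reversals_to_average:]))
    elif reversal_tmrs.size:
        warnings.warn(
            f"track ended with only {reversal_tmrs.size} reversals; "
            "SRT computed from those available",
            stacklevel=2,
        )
        srt = float(np.mean(reversal_tmrs))
    else:
        warnings.warn("track produced no reversals; SRT undefined", stacklevel=2)
        srt = float("nan")
    return StaircaseTrace(
        tmr_db=np.asarray(tmrs),
        correct=np.asarray(corrects),
        reversal=reversal_arr,
        step_db=np.asarray(steps),
        srt_db=srt,
        n_trials=len(tmrs),
        converged=converged,
    )


def run_track(observer, condition: ListeningCondition, spatial: str,
              corpus: Optional[Corpus], cfg: StaircaseConfig = StaircaseConfig(),
              seed: int = 0, renderer=None) -> StaircaseTrace:
    """Measure one SRT: a full adaptive track for one condition cell."""
    from .pipeline import run_trial

    if spatial not in SPATIAL_CONFIGS:
        raise ValueError(f"unknown spatial configuration {spatial!r}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7001]))

    def respond(tmr_db: float) -> bool:
        scene = SceneConfig.from_name(spatial, tmr_db=tmr_db)
        return run_trial(observer, corpus, condition, scene, rng, renderer)

    return run_staircase(respond, cfg)


def run_experiment(conditions: Sequence, spatial_configs: Sequence[str],
                   n_blocks: int, observer, seed: int = 0,
                   corpus: Optional[Corpus] = None,
                   cfg: StaircaseConfig = StaircaseConfig(),
                   renderer=None) -> pd.DataFrame:
    """Run the full condition x spatial grid over test blocks.

    Cells are randomized within each block (fresh order per block), one
    track per cell per block.  Returns a tidy table with one row per
    track: block, condition, spatial, srt_db, n_trials, converged.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    conditions = [
        c if isinstance(c, ListeningCondition) else condition_preset(c)
        for c in conditions
    ]
    order_rng = np.random.default_rng(np.random.SeedSequence([seed, 9001]))
    cells = [(c, s) for c in conditions for s in spatial_configs]
    rows = []
    track_id = 0
    for block in range(1, n_blocks + 1):
        perm = order_rng.permutation(len(cells))
        for j in perm:
            condition, spatial = cells[j]
            trace = run_track(
                observer, condition, spatial, corpus, cfg,
                seed=int(np.random.SeedSequence([seed, block, int(j)]).generate_state(1)[0] % (2**31)),
                renderer=renderer,
            )
            rows.append(
                {
                    "block": block,
                    "condition": condition.name,
                    "spatial": spatial,
                    "srt_db": trace.srt_db,
                    "n_trials": trace.n_trials,
                    "converged": trace.converged,
                }
            )
            track_id += 1
    return pd.DataFrame(rows)
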