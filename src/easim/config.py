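"""YAML experiment configuration for the command-line runner."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

import yaml

from .place_map import PRESET_NAMES
from .spatial_scene import SPATIAL_CONFIGS
from .staircase import StaircaseConfig


@dataclass(frozen=True)
class ExperimentConfig:
    conditions: List[str] = field(default_factory=lambda: list(PRESET_NAMES))
    spatial_configs: List[str] = field(default_factory=lambda: list(SPATIAL_CONFIGS))
    n_blocks: int = 2
    seed: int = 0
    rate: int = 44_100
    observer: str = "oracle"          # "oracle" | "template"
    oracle_threshold_db: float = 5.0
    oracle_slope_per_db: float = 1.0
    staircase: StaircaseConfig = field(default_factory=StaircaseConfig)

    def __post_init__(self) -> None:
        unknown = set(self.conditions) - set(PRESET_NAMES)
        if unknown:
            raise ValueError(f"unknown conditions: {sorted(unknown)}")
        unknown = set(self.spatial_configs) - set(SPATIAL_CONFIGS)
        if unknown:
            raise ValueError(f"unknown spatial configs: {sorted(unknown)}")
        if self.observer not in ("oracle", "template"):
            raise ValueError("observer must be 'oracle' or 'template'")


def load_experiment_config(path: str) -> ExperimentConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    stair_raw = raw.pop("staircase", {})
    return ExperimentConfig(staircase=StaircaseConfig(**stair_raw), **raw)
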