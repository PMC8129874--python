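"""Run configuration: defaults, YAML loading and validation."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .placements import DEFAULT_USABILITY_ORDER, PLACEMENTS


@dataclass(frozen=True)
class CohortConfig:
    n_participants: int = 6
    n_activities: int = 8
    n_sedentary: int = 2
    n_locomotion: int = 3
    duration_lo: float = 360.0
    duration_hi: float = 480.0
    drop_probability: float = 0.0
    vo2_noise_sd: float = 0.5
    sample_rate: float = 100.0
    roster_seed: int = 0
    placements: tuple[str, ...] = PLACEMENTS


@dataclass(frozen=True)
class WindowConfig:
    window_s: float = 16.0


@dataclass(frozen=True)
class MetabolicConfig:
    onset_s: float = 120.0
    smooth_half_width_s: float = 15.0
    min_breaths: int = 10


@dataclass(frozen=True)
class ExperimentConfig:
    n_outer: int = 6
    n_inner: int = 5
    n_estimators: int = 300
    max_features: tuple = ("sqrt", 0.3333)
    min_samples_leaf: tuple = (1, 5)

    def hyper_grid(self) -> dict[str, list]:
        return {
            "n_estimators": [self.n_estimators],
            "max_features": list(self.max_features),
            "min_samples_leaf": list(self.min_samples_leaf),
        }


@dataclass(frozen=True)
class EvaluationConfig:
    margin: float = 0.10
    margin_mode: str = "relative"
    rule: str = "fewest_first"
    usability_order: tuple[str, ...] = DEFAULT_USABILITY_ORDER


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    windowing: WindowConfig = field(default_factory=WindowConfig)
    metabolic: MetabolicConfig = field(default_factory=MetabolicConfig)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)


_SECTIONS = {
    "cohort": CohortConfig,
    "windowing": WindowConfig,
    "metabolic": MetabolicConfig,
    "experiment": ExperimentConfig,
    "evaluation": EvaluationConfig,
}


def load_config(path: str | Path | None = None, seed: int | None = None) -> RunConfig:
    """Build a RunConfig from defaults, optional YAML overrides, and an
    explicit seed. Unknown keys raise so typos do not silently revert to
    defaults; a seed must come from somewhere (file or CLI)."""
    data = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}

    cfg = RunConfig()
    for section, payload in data.items():
        if section == "seed":
            cfg = replace(cfg, seed=int(payload))
            continue
        if section not in _SECTIONS:
            raise ValueError(f"unknown config section {section!r}")
        current = getattr(cfg, section)
        known = current.__dataclass_fields__
        unknown = set(payload) - set(known)
        if unknown:
            raise ValueError(f"unknown keys in [{section}]: {sorted(unknown)}")
        coerced = {
            k: tuple(v) if isinstance(v, list) and isinstance(getattr(current, k), tuple) else v
            for k, v in payload.items()
        }
        cfg = replace(cfg, **{section: replace(current, **coerced)})
    if seed is not None:
        cfg = replace(cfg, seed=int(seed))
    return cfg
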