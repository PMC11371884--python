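"""Run configuration: one YAML file holding every tunable, strictly parsed."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import yaml

from .augmentation import AugmentationConfig
from .classifier import NetworkSpec, PredictionConfig, TrainingConfig


@dataclass(frozen=True)
class DirectionConfig:
    n: int = 198
    construction: str = "fibonacci_hemisphere"
    reference_radius_mm: float = 1.0


@dataclass(frozen=True)
class EvaluationConfig:
    k: int = 5
    epochs: Optional[int] = None  # None -> TrainingConfig.epochs


@dataclass(frozen=True)
class RunConfig:
    directions: DirectionConfig = field(default_factory=DirectionConfig)
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    network: NetworkSpec = field(default_factory=NetworkSpec)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    prediction: PredictionConfig = field(default_factory=PredictionConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    master_seed: int = 0
    log_level: str = "INFO"


_SECTIONS = {
    "directions": DirectionConfig,
    "augmentation": AugmentationConfig,
    "network": NetworkSpec,
    "training": TrainingConfig,
    "prediction": PredictionConfig,
    "evaluation": EvaluationConfig,
}


def _build(cls, mapping: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(
            f"unknown config keys for {cls.__name__}: {sorted(unknown)}"
        )
    if cls is NetworkSpec and "hidden_sizes" in mapping:
        mapping = dict(mapping, hidden_sizes=tuple(mapping["hidden_sizes"]))
    return cls(**mapping)


def load_config(path: Optional[str] = None) -> RunConfig:
    """Load a YAML config; missing sections fall back to defaults."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    kwargs = {}
    for key, value in raw.items():
        if key in _SECTIONS:
            kwargs[key] = _build(_SECTIONS[key], value or {})
        elif key in ("master_seed", "log_level"):
            kwargs[key] = value
        else:
            raise ValueError(f"unknown top-level config key {key!r}")
    return RunConfig(**kwargs)
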