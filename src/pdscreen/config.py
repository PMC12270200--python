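"""Experiment configuration: a declarative YAML document with one section
per pipeline stage, validated strictly (unknown keys and type mismatches
are rejected, all problems reported at once) and with defaults filled."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synthetic_cohort import CohortConfig

__all__ = [
    "ExperimentConfig", "ConfigError", "load_config", "save_config",
    "PreprocessSection", "SplitSection", "TaskSection", "FusionSection",
    "EvaluationSection",
]


class ConfigError(ValueError):
    """One or more problems in an experiment configuration."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(self.problems))


@dataclass
class PreprocessSection:
    scaler: str = "standardize"             # standardize | minmax
    corr_threshold: float | None = None     # None disables selection
    smote_ratio: float | None = None        # None disables oversampling
    smote_k: int = 5
    duration_sd_limit: float = 3.0


@dataclass
class SplitSection:
    test_size: int = 60
    dev_size: int = 40
    restarts: int = 20
    max_stale: int = 500
    pd_fraction: float = 0.5


@dataclass
class TaskSection:
    budget: int = 1
    hidden_dims: tuple = (32,)
    dropout_p: float = 0.2
    learning_rate: float = 0.01
    batch_size: int = 128
    epochs: int = 60
    optimizer: str = "adamw"
    momentum: float = 0.9
    T: int = 30


@dataclass
class FusionSection:
    budget: int = 1
    projection_dim: int = 128
    query_dim: int = 32
    hidden_dim: int = 16
    dropout_p: float = 0.2
    eta: float = 1.0
    T: int = 30
    learning_rate: float = 0.005
    batch_size: int = 128
    epochs: int = 80
    optimizer: str = "adamw"
    momentum: float = 0.9
    decision_threshold: float = 0.5
    ci_level: float = 0.95


@dataclass
class EvaluationSection:
    bootstrap_B: int = 1000
    ci_level: float = 0.95
    ece_bins: int = 10


@dataclass
class ExperimentConfig:
    seed: int = 0
    verbosity: int = 1
    cohort: CohortConfig = field(default_factory=CohortConfig)
    preprocess: PreprocessSection = field(default_factory=PreprocessSection)
    split: SplitSection = field(default_factory=SplitSection)
    task: TaskSection = field(default_factory=TaskSection)
    fusion: FusionSection = field(default_factory=FusionSection)
    evaluation: EvaluationSection = field(default_factory=EvaluationSection)


_SECTIONS = {"cohort": CohortConfig, "preprocess": PreprocessSection,
             "split": SplitSection, "task": TaskSection,
             "fusion": FusionSection, "evaluation": EvaluationSection}

# dataclass fields whose defaults are tuples (YAML yields lists)
_TUPLE_FIELDS = {"sessions_per_participant", "stage_thresholds", "hidden_dims"}


def _build_section(cls, data: dict, prefix: str, problems: list):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in fields:
            problems.append(f"unknown key {prefix}{key!r}")
            continue
        if key in _TUPLE_FIELDS and isinstance(value, list):
            value = tuple(value)
        default = fields[key].default
        if isinstance(default, bool) and not isinstance(value, bool):
            problems.append(f"{prefix}{key}: expected bool, got {type(value).__name__}")
            continue
        if isinstance(default, int) and not isinstance(default, bool) \
                and not isinstance(value, int) and value is not None:
            # floats standing in for ints are a type mismatch
            if isinstance(value, float) and not value.is_integer():
                problems.append(f"{prefix}{key}: expected int, got {value}")
                continue
            if isinstance(value, float):
                value = int(value)
            elif not isinstance(value, (int,)):
                problems.append(
                    f"{prefix}{key}: expected int, got {type(value).__name__}")
                continue
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except TypeError as e:
        problems.append(f"{prefix}: {e}")
        return cls()


def config_from_dict(data: dict) -> ExperimentConfig:
    if not isinstance(data, dict):
        raise ConfigError(["document root must be a mapping"])
    problems: list[str] = []
    kwargs = {}
    for key, value in data.items():
        if key in _SECTIONS:
            if not isinstance(value, dict):
                problems.append(f"section {key!r} must be a mapping")
                continue
            kwargs[key] = _build_section(_SECTIONS[key], value, f"{key}.", problems)
        elif key in ("seed", "verbosity"):
            if not isinstance(value, int) or isinstance(value, bool):
                problems.append(f"{key}: expected int, got {type(value).__name__}")
            else:
                kwargs[key] = value
        else:
            problems.append(f"unknown key {key!r}")
    if problems:
        raise ConfigError(problems)
    return ExperimentConfig(**kwargs)


def load_config(path) -> ExperimentConfig:
    """Parse and validate a YAML experiment configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = config_from_dict(data)
    try:
        cfg.cohort.validate()
    except ValueError as e:
        raise ConfigError([f"cohort: {e}"]) from e
    return cfg


def config_to_dict(cfg: ExperimentConfig) -> dict:
    d = dataclasses.asdict(cfg)

    def detuple(obj):
        if isinstance(obj, tuple):
            return [detuple(x) for x in obj]
        if isinstance(obj, list):
            return [detuple(x) for x in obj]
        if isinstance(obj, dict):
            return {k: detuple(v) for k, v in obj.items()}
        return obj

    return detuple(d)


def save_config(cfg: ExperimentConfig, path) -> None:
    """Write the normalized configuration (defaults filled) as YAML."""
    Path(path).write_text(
        yaml.safe_dump(config_to_dict(cfg), sort_keys=True))
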