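"""YAML run configuration: strict parsing into per-stage config objects.

A run config is a nested mapping with optional blocks ``synthetic``,
``preprocess``, ``features``, ``model``, ``stamina``, ``bias`` and
``control`` plus the globals ``seed``, ``out_dir`` and ``log_level``.
Unknown keys are rejected (typos should fail loudly, not silently fall back
to defaults).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .control import AthleteState, ControlConfig, TrainingParams
from .exceptions import ConfigError
from .features import FeatureConfig
from .preprocess import PreprocessConfig
from .synthetic import SyntheticConfig


@dataclass
class ModelConfig:
    family: str = "extra_trees"
    threshold: float = 0.5
    cv_scheme: str = "subject"
    n_splits: int = 5
    hyperparameters: dict = field(default_factory=dict)


@dataclass
class StaminaConfig:
    channel: str = "accel_mag"
    band: int | None = None
    thresholds: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0)


@dataclass
class BiasConfig:
    epsilon: float = 1e-3
    max_iter: int = 10
    top_k: int = 3


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "out"
    log_level: str = "INFO"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    stamina: StaminaConfig = field(default_factory=StaminaConfig)
    bias: BiasConfig = field(default_factory=BiasConfig)
    control: ControlConfig = field(default_factory=ControlConfig)
    athlete: AthleteState = field(default_factory=AthleteState)
    training: TrainingParams = field(default_factory=TrainingParams)


def _build(cls, block: dict, where: str):
    if not isinstance(block, dict):
        raise ConfigError(f"block {where!r} must be a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - names
    if unknown:
        raise ConfigError(f"unknown keys in {where!r}: {sorted(unknown)}")
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name not in block:
            continue
        v = block[f.name]
        if isinstance(v, list):
            v = tuple(v)
        coerced[f.name] = v
    try:
        return cls(**coerced)
    except TypeError as exc:
        raise ConfigError(f"invalid block {where!r}: {exc}") from exc


_BLOCKS = {
    "synthetic": SyntheticConfig,
    "preprocess": PreprocessConfig,
    "features": FeatureConfig,
    "model": ModelConfig,
    "stamina": StaminaConfig,
    "bias": BiasConfig,
    "control": ControlConfig,
    "athlete": AthleteState,
    "training": TrainingParams,
}
_GLOBALS = ("seed", "out_dir", "log_level")


def parse_run_config(raw: dict | None) -> RunConfig:
    raw = raw or {}
    if not isinstance(raw, dict):
        raise ConfigError("run config must be a mapping at top level")
    unknown = set(raw) - set(_BLOCKS) - set(_GLOBALS)
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    kwargs: dict = {k: raw[k] for k in _GLOBALS if k in raw}
    for name, cls in _BLOCKS.items():
        if name in raw:
            kwargs[name] = _build(cls, raw[name], name)
    cfg = RunConfig(**kwargs)
    # blocks that carry their own validation
    cfg.synthetic.validate()
    cfg.preprocess.validate()
    cfg.control.validate()
    cfg.athlete.validate()
    return cfg


def load_run_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML run config; None yields pure defaults."""
    if path is None:
        return RunConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        loc = f" (line {mark.line + 1})" if mark else ""
        raise ConfigError(f"malformed YAML in {path}{loc}: {exc}") from exc
    return parse_run_config(raw)


def config_hash(cfg: RunConfig) -> str:
    """Stable sha256 over the canonical JSON form of the config."""
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()
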