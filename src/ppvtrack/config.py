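"""YAML configuration files mapping 1:1 onto :class:`~ppvtrack.model.ModelConfig`."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import yaml

from .model import ConfigError, ModelConfig

__all__ = ["load_config", "save_config", "config_from_file_or_signal"]

_FIELDS = {f.name for f in dataclasses.fields(ModelConfig)}


def load_config(path: str | Path, **overrides) -> ModelConfig:
    """Load a ModelConfig from a YAML key-value file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - _FIELDS
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    raw.update(overrides)
    return ModelConfig(**raw)


def save_config(cfg: ModelConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=False))


def config_from_file_or_signal(path: str | Path | None, signal: np.ndarray,
                               sample_rate: float, **overrides) -> ModelConfig:
    """Config for a tracking run: from a file if given, else the
    signal-dependent design-table defaults."""
    if path is not None:
        return load_config(path, **overrides)
    return ModelConfig.from_signal(signal, sample_rate, **overrides)
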