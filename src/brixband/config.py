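"""Run configuration: YAML schema with strict key validation.

Every command-line run is driven by (or snapshots to) a flat-sectioned YAML
document. Unknown keys are rejected so a typo cannot silently fall back to
a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .phantom import PhantomConfig
from .trainer import StagePlan


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs/latest"
    manifest: str | None = None
    K: int = 56
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    plan: StagePlan = field(default_factory=StagePlan)
    split_ratio: tuple[float, float, float] = (8, 1, 1)
    ssim_mode: str = "global"


def _coerce_section(cls, data: dict, section: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in '{section}': {sorted(unknown)}")
    kwargs = dict(data)
    for f in fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            kwargs[f.name] = tuple(kwargs[f.name])
        if f.name == "informative_bands" and kwargs.get(f.name) is not None:
            kwargs[f.name] = frozenset(kwargs[f.name])
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    allowed = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in raw.items():
        if key == "phantom":
            kwargs[key] = _coerce_section(PhantomConfig, value or {}, key)
        elif key == "plan":
            kwargs[key] = _coerce_section(StagePlan, value or {}, key)
        elif key == "split_ratio":
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    cfg = RunConfig(**kwargs)
    cfg.phantom.validate()
    return cfg


def snapshot_config(cfg: RunConfig, path) -> None:
    """Write the fully resolved configuration next to the run outputs."""

    def plain(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: plain(getattr(obj, f.name))
                    for f in fields(obj)}
        if isinstance(obj, frozenset):
            return sorted(obj)
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(plain(cfg), fh, sort_keys=False)
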