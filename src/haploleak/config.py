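"""Structured experiment configuration with strict key checking.

A run is described by nested blocks mirroring the module parameter
objects plus a global seed; unknown keys are rejected so typos cannot
silently fall back to defaults. Every CLI run persists the resolved
configuration next to its outputs for provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .attack import AttackConfig
from .engine import EngineParams
from .linking import LinkingConfig
from .popgen import ConfigurationError
from .relatives import WFParams

__all__ = ["ExperimentConfig", "derive_seed"]

_BLOCKS = {
    "attack": AttackConfig,
    "engine": EngineParams,
    "linking": LinkingConfig,
    "relative_model": WFParams,
}


def _strict_build(cls, data: dict, where: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigurationError(f"unknown keys in {where}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class ExperimentConfig:
    seed: int = 0
    attack: AttackConfig = field(default_factory=AttackConfig)
    engine: EngineParams = field(default_factory=EngineParams)
    linking: LinkingConfig = field(default_factory=LinkingConfig)
    relative_model: WFParams = field(default_factory=WFParams)
    paths: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        data = dict(data or {})
        kwargs = {}
        for name, block_cls in _BLOCKS.items():
            if name in data:
                kwargs[name] = _strict_build(block_cls, data.pop(name) or {}, name)
        kwargs["seed"] = int(data.pop("seed", 0))
        kwargs["paths"] = dict(data.pop("paths", {}) or {})
        if data:
            raise ConfigurationError(f"unknown top-level keys: {sorted(data)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        out = {"seed": self.seed, "paths": dict(self.paths)}
        for name in _BLOCKS:
            out[name] = dataclasses.asdict(getattr(self, name))
        return out

    def dump(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def derive_seed(root_seed: int, component: str) -> int:
    """Stable per-component child seed from one root seed (< 2**31)."""
    h = 2166136261
    for ch in f"{component}:{root_seed}":
        h = (h ^ ord(ch)) * 16777619 % (2**32)
    return h % (2**31)
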