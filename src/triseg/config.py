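"""Run configuration: one YAML file fully determines a run.

The file mirrors the dataclass tree (phantom / train {loss, sampler,
network} / consensus, plus the master seed).  Unknown keys are rejected by
name so typos fail loudly rather than silently using a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, is_dataclass
from pathlib import Path
from typing import Any, get_args, get_origin

import yaml

from .exceptions import ConfigError
from .inference import ConsensusConfig
from .phantoms import PhantomSpec
from .training import TrainConfig


def _coerce(value: Any, anno: Any, path: str) -> Any:
    if is_dataclass(anno):
        if not isinstance(value, dict):
            raise ConfigError(f"expected a mapping at '{path}', got {type(value).__name__}")
        return dataclass_from_dict(anno, value, path)
    if get_origin(anno) is tuple and isinstance(value, (list, tuple)):
        args = get_args(anno)
        elem = args[0] if args else None
        if elem in (int, float):
            return tuple(elem(v) for v in value)
        return tuple(value)
    return value


def dataclass_from_dict(cls, data: dict, path: str = "") -> Any:
    """Build a (possibly nested) dataclass from a mapping, strictly."""
    if not isinstance(data, dict):
        raise ConfigError(f"expected a mapping at '{path or cls.__name__}', got {type(data).__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"unknown config key(s) at '{path or cls.__name__}': {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        f = fields[name]
        sub_path = f"{path}.{name}" if path else name
        anno = f.type if not isinstance(f.type, str) else _resolve_annotation(cls, name)
        kwargs[name] = _coerce(value, anno, sub_path)
    return cls(**kwargs)


def _resolve_annotation(cls, name: str):
    import typing

    hints = typing.get_type_hints(cls)
    return hints.get(name)


def _to_plain(obj: Any) -> Any:
    if is_dataclass(obj):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (list, dict)):
        raise ConfigError("nested containers other than tuples are not serialized")
    return obj


@dataclass
class RunConfig:
    """Top-level configuration: seed fans out to every component."""

    seed: int = 0
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    consensus: ConsensusConfig = field(default_factory=ConsensusConfig)

    def validate(self) -> None:
        self.phantom.validate()
        self.train.validate()
        self.consensus.validate()

    def reseeded(self) -> "RunConfig":
        """Propagate the master seed into sub-configs that carry their own."""
        train = dataclasses.replace(
            self.train,
            seed=self.seed,
            sampler=dataclasses.replace(self.train.sampler, seed=self.seed + 1),
            network=dataclasses.replace(self.train.network, seed=self.seed + 2),
        )
        return dataclasses.replace(self, train=train)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_to_plain(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if data is None:
            data = {}
        cfg = dataclass_from_dict(cls, data)
        cfg.validate()
        return cfg
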