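"""Run configuration: one YAML schema covering network, training,
augmentation and simulation; unknown keys are rejected with their key path,
missing keys fall back to defaults, and dump(parse(x)) round-trips."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .blocks import MDEConfig
from .network import DiscConfig, FiLMConfig, GateConfig, NetworkConfig
from .synthetic import SynthParams
from .training import AugmentSpec, TrainConfig

__all__ = ["RunConfig", "parse_config", "dump_config", "config_to_dict"]


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    network: NetworkConfig = field(default_factory=NetworkConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    augment: AugmentSpec = field(default_factory=AugmentSpec)
    simulate: SynthParams = field(default_factory=SynthParams)

    def validate(self):
        self.network.validate()
        self.train.validate()
        self.augment.validate()
        self.simulate.validate()


_NESTED: dict[type, dict[str, type]] = {
    RunConfig: {"network": NetworkConfig, "train": TrainConfig,
                "augment": AugmentSpec, "simulate": SynthParams},
    NetworkConfig: {"mde": MDEConfig, "tradesgate": GateConfig,
                    "atfilm": FiLMConfig, "discriminator": DiscConfig},
}
_TUPLE_FIELDS = {"dilation_rates", "radius_range", "eccentricity_range"}


def _from_dict(cls: type, d: dict, path: str):
    if d is None:
        d = {}
    if not isinstance(d, dict):
        raise ValueError(f"config section '{path or '<root>'}' must be a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        where = f"{path}.{sorted(unknown)[0]}" if path else sorted(unknown)[0]
        raise ValueError(f"unknown config key: {where}")
    nested = _NESTED.get(cls, {})
    kwargs = {}
    for key, val in d.items():
        sub = f"{path}.{key}" if path else key
        if key in nested:
            kwargs[key] = _from_dict(nested[key], val, sub)
        elif key in _TUPLE_FIELDS and isinstance(val, list):
            kwargs[key] = tuple(val)
        else:
            kwargs[key] = val
    return cls(**kwargs)


def config_to_dict(cfg) -> dict:
    def conv(v):
        if dataclasses.is_dataclass(v):
            return {k: conv(getattr(v, k)) for k in
                    (f.name for f in dataclasses.fields(v))}
        if isinstance(v, tuple):
            return [conv(x) for x in v]
        return v
    return conv(cfg)


def parse_config(source) -> RunConfig:
    """Parse a YAML file (path) or an already-loaded mapping; an empty file
    yields the all-defaults configuration."""
    if isinstance(source, (str, Path)):
        data = yaml.safe_load(Path(source).read_text())
    else:
        data = source
    cfg = _from_dict(RunConfig, data or {}, "")
    cfg.validate()
    return cfg


def dump_config(cfg: RunConfig) -> str:
    return yaml.safe_dump(config_to_dict(cfg), sort_keys=False)
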