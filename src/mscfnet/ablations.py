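"""Named single-modification variants of the full model, for controlled
component ablations.  Each variant changes exactly one architectural or
regularization choice relative to the full configuration."""

from __future__ import annotations

import dataclasses

from .blocks import MDEConfig
from .network import NetworkConfig

__all__ = ["VARIANTS", "apply_variant"]


def _mde(cfg: NetworkConfig, **kw) -> NetworkConfig:
    return dataclasses.replace(cfg, mde=dataclasses.replace(cfg.mde, **kw))


def _gate(cfg: NetworkConfig, **kw) -> NetworkConfig:
    return dataclasses.replace(cfg, tradesgate=dataclasses.replace(cfg.tradesgate, **kw))


def _film(cfg: NetworkConfig, **kw) -> NetworkConfig:
    return dataclasses.replace(cfg, atfilm=dataclasses.replace(cfg.atfilm, **kw))


VARIANTS: dict[str, callable] = {
    "full": lambda c: c,
    # plain-convolution baseline: standard blocks, no gate, concatenation skips
    "unet_baseline": lambda c: _film(_gate(_mde(
        c, **dataclasses.asdict(MDEConfig.standard_conv())), enabled=False),
        mode="concat"),
    # MDE variants
    "mde_single_scale": lambda c: _mde(c, n_branches=1, dilation_rates=(1,)),
    "mde_no_se": lambda c: _mde(c, use_se=False),
    "mde_single_rate_d2": lambda c: _mde(
        c, dilation_rates=tuple(2 for _ in range(c.mde.n_branches))),
    "mde_standard_conv": lambda c: _mde(
        c, n_branches=1, dilation_rates=(1,), use_se=False),
    # gate variants
    "tradesgate_removed": lambda c: _gate(c, enabled=False),
    "tradesgate_no_tv": lambda c: _gate(c, tv_weight=0.0),
    "tradesgate_simple": lambda c: _gate(c, simple_gate=True),
    "tradesgate_eps001": lambda c: _gate(c, epsilon=0.01),
    # FiLM variants
    "atfilm_beta_only": lambda c: _film(c, mode="beta_only"),
    "atfilm_gamma_only": lambda c: _film(c, mode="gamma_only"),
    "atfilm_no_adv": lambda c: _film(c, epsilon=0.0),
    "atfilm_concat": lambda c: _film(c, mode="concat"),
}


def apply_variant(cfg: NetworkConfig, name: str) -> NetworkConfig:
    if name not in VARIANTS:
        raise KeyError(f"unknown variant '{name}'; choose from {sorted(VARIANTS)}")
    out = VARIANTS[name](cfg)
    out.validate()
    return out
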