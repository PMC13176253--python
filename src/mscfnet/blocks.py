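"""Multi-scale Differential Enhancement (MDE) block.

The basic feature unit of the network: parallel dilated-convolution branches
at different effective receptive fields, channel-concatenated and projected
back to the input width, reweighted by a squeeze-and-excitation style channel
gate, and added back to the input through a residual connection:

    F_k  = T_k(F)                 (branch k, bias-free conv -> rectifier)
    F*   = proj(concat_k F_k)
    F~   = F* (.) gamma(F*) + F

The branch stage is positively homogeneous (T_k(aF) = a T_k(F) for a > 0)
because the branch convolutions carry no bias and the rectifier commutes
with positive scaling; normalization is applied between blocks, not inside
the branches.  With a single branch at dilation 1 and the channel gate
disabled, the block reduces exactly to a plain residual conv unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Conv2d, Linear, Module, Tensor, concat

__all__ = ["MDEConfig", "SEGate", "MDEBlock", "se_reweight", "mde_forward"]


@dataclass(frozen=True)
class MDEConfig:
    """Hyperparameters of one MDE block.

    dilation_rates spans local-to-regional receptive fields; the default
    (1, 2, 4) gives three branches.  se_reduction is the channel bottleneck
    ratio of the reweighting gate (hidden width clamped to >= 1).
    """

    n_branches: int = 3
    kernel_size: int = 3
    dilation_rates: tuple[int, ...] = (1, 2, 4)
    se_reduction: int = 4
    use_se: bool = True
    residual: bool = True

    def validate(self):
        if len(self.dilation_rates) != self.n_branches:
            raise ValueError("need one dilation rate per branch")
        if any(d < 1 for d in self.dilation_rates):
            raise ValueError("dilation rates must be >= 1")
        if self.n_branches < 1:
            raise ValueError("n_branches must be >= 1")

    @staticmethod
    def single_rate(d: int = 2) -> "MDEConfig":
        """Single-branch, single-dilation ablation."""
        return MDEConfig(n_branches=1, dilation_rates=(d,))

    @staticmethod
    def standard_conv() -> "MDEConfig":
        """Plain residual conv ablation: one branch, dilation 1, no gate."""
        return MDEConfig(n_branches=1, dilation_rates=(1,), use_se=False)


class SEGate(Module):
    """Squeeze-and-excitation channel gate: global average pool ->
    bottleneck two-layer map -> logistic; outputs in (0, 1) per channel."""

    def __init__(self, c: int, reduction: int, *, rng: np.random.Generator):
        hidden = max(c // reduction, 1)
        self.fc1 = Linear(c, hidden, rng=rng)
        self.fc2 = Linear(hidden, c, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        b, c = x.shape[0], x.shape[1]
        pooled = x.mean(axis=(2, 3)).reshape(b, c)
        w = self.fc2(self.fc1(pooled).relu()).sigmoid()
        return w.reshape(b, c, 1, 1)


def se_reweight(fstar: Tensor, gate: SEGate) -> Tensor:
    """Per-channel weights in (0,1), broadcastable over H x W."""
    return gate(fstar)


class MDEBlock(Module):
    def __init__(self, c: int, cfg: MDEConfig | None = None, *,
                 rng: np.random.Generator):
        cfg = cfg or MDEConfig()
        cfg.validate()
        self.cfg = cfg
        self.branches = [
            Conv2d(c, c, cfg.kernel_size, dilation=d, bias=False, rng=rng)
            for d in cfg.dilation_rates
        ]
        # channel projection back to C only needed when branches widen the map
        self.proj = (Conv2d(c * cfg.n_branches, c, 1, bias=False, rng=rng)
                     if cfg.n_branches > 1 else None)
        self.se = SEGate(c, cfg.se_reduction, rng=rng) if cfg.use_se else None

    def branch_stage(self, f: Tensor) -> Tensor:
        """F* : concat of branch outputs, projected back to C channels."""
        outs = [b(f).relu() for b in self.branches]
        fstar = concat(outs, axis=1) if len(outs) > 1 else outs[0]
        if self.proj is not None:
            fstar = self.proj(fstar)
        return fstar

    def forward(self, f: Tensor) -> Tensor:
        if f.shape[1] != self.branches[0].weight.shape[1]:
            raise ValueError(
                f"channel mismatch: block expects {self.branches[0].weight.shape[1]}, "
                f"got {f.shape[1]}")
        fstar = self.branch_stage(f)
        out = fstar * self.se(fstar) if self.se is not None else fstar
        if self.cfg.residual:
            out = out + f
        return out


def mde_forward(f: Tensor, block: MDEBlock) -> Tensor:
    """Functional alias for MDEBlock.forward."""
    return block(f)
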