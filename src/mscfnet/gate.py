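"""TRADESGate: adversarially regularized spatial gated fusion.

A single-channel gate g in [0,1] (logistic of a 1x1 convolution over the
concatenated main/auxiliary features) mixes the two feature fields as a
spatially varying convex combination

    f = g (.) f_m + (1 - g) (.) f_a .

Two regularizers shape the gate: an anisotropic total-variation penalty that
keeps the mixing pattern spatially smooth, and a prediction-consistency term
KL( p(f) || p(f~) ) in which f~ is the fusion state under the worst-case
bounded perturbation of the gate found by projected sign-gradient ascent
(TRADES-style inner maximization).  The perturbation is additive on the
squashed [0,1] gate scale, lives in an infinity-norm ball of radius epsilon,
and never touches the input image or backbone features.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .nn import Conv2d, Module, Tensor, concat

__all__ = ["GateState", "PerturbConfig", "TRADESGate", "gate_fuse",
           "tv_penalty", "kl_consistency", "adversarial_gate_perturbation"]


@dataclass
class GateState:
    """Gate field of one fusion site: squashed gate, its logits, and the
    current bounded perturbation (all 1-channel rasters, batch-leading)."""

    gate: np.ndarray                  # (B,1,H,W) in [0,1]
    gate_logits: np.ndarray           # (B,1,H,W)
    perturbation: np.ndarray | None = None   # ||.||_inf <= epsilon

    def perturbed_gate(self) -> np.ndarray:
        if self.perturbation is None:
            return self.gate
        return np.clip(self.gate + self.perturbation, 0.0, 1.0)


@dataclass(frozen=True)
class PerturbConfig:
    """Inner-maximization settings shared by the gate and FiLM pathways."""

    epsilon: float = 0.03
    n_steps: int = 1
    step_size: float | None = None    # defaults to epsilon / n_steps
    target: str = "gate"              # "gate" | "film"

    def validate(self):
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.epsilon > 0 and self.n_steps < 1:
            raise ValueError("n_steps must be >= 1 when epsilon > 0")
        if self.target not in ("gate", "film"):
            raise ValueError("target must be 'gate' or 'film'")

    @property
    def effective_step(self) -> float:
        return self.step_size if self.step_size is not None else self.epsilon / max(self.n_steps, 1)


class TRADESGate(Module):
    """Computes the gate from [f_m ; f_a] and applies the convex fusion."""

    def __init__(self, c: int, *, rng: np.random.Generator):
        self.conv = Conv2d(2 * c, 1, 1, rng=rng)

    def logits(self, fm: Tensor, fa: Tensor) -> Tensor:
        return self.conv(concat([fm, fa], axis=1))

    def forward(self, fm: Tensor, fa: Tensor,
                gate_override: Tensor | None = None) -> tuple[Tensor, Tensor, Tensor]:
        """Returns (fused, gate, logits); gate_override substitutes the gate
        field (e.g. a perturbed one) without recomputing logits."""
        logits = self.logits(fm, fa)
        gate = logits.sigmoid() if gate_override is None else gate_override
        return gate_fuse(fm, fa, gate), gate, logits


def gate_fuse(fm: Tensor, fa: Tensor, gate: Tensor) -> Tensor:
    """f = g*f_m + (1-g)*f_a with the 1-channel gate broadcast over channels."""
    if fm.shape != fa.shape:
        raise ValueError(f"feature shape mismatch: {fm.shape} vs {fa.shape}")
    if gate.shape[-2:] != fm.shape[-2:]:
        raise ValueError("gate spatial size must match the features")
    return gate * fm + (1.0 - gate) * fa


def tv_penalty(gate: Tensor | np.ndarray, reduction: str = "mean") -> Tensor:
    """Anisotropic total variation of the gate raster: |horizontal neighbor
    diffs| + |vertical neighbor diffs|, mean (default) or sum form."""
    g = gate if isinstance(gate, Tensor) else Tensor(np.asarray(gate, dtype=np.float32))
    if reduction not in ("mean", "sum"):
        raise ValueError("reduction must be 'mean' or 'sum'")
    h = g[..., :, 1:] - g[..., :, :-1]
    v = g[..., 1:, :] - g[..., :-1, :]
    terms = []
    for d in (h, v):
        if d.data.size:
            terms.append(d.abs().mean() if reduction == "mean" else d.abs().sum())
    if not terms:
        return Tensor(np.float32(0.0))
    out = terms[0]
    for t in terms[1:]:
        out = out + t
    return out


def _as_prob_tensor(p, name: str, tol: float = 1e-5) -> Tensor:
    t = p if isinstance(p, Tensor) else Tensor(np.asarray(p, dtype=np.float32))
    if t.data.min() < -tol:
        raise ValueError(f"{name} has negative entries")
    sums = t.data.sum(axis=-3)
    if np.abs(sums - 1.0).max() > tol:
        raise ValueError(f"{name} is not normalized per pixel (max dev "
                         f"{np.abs(sums - 1.0).max():.2e})")
    return t


def kl_consistency(p_clean, p_pert, eps: float = 1e-8) -> Tensor:
    """Per-pixel KL( p_clean || p_pert ), averaged over pixels (and batch).

    The direction is fixed clean -> perturbed.  Accepts (K,H,W) or (B,K,H,W)
    probability maps as Tensors or arrays; raises on non-normalized input.
    """
    pc = _as_prob_tensor(p_clean, "p_clean")
    pp = _as_prob_tensor(p_pert, "p_pert")
    if pc.shape != pp.shape:
        raise ValueError(f"shape mismatch: {pc.shape} vs {pp.shape}")
    ax = pc.ndim - 3
    per_pixel = (pc * ((pc + eps).log() - (pp + eps).log())).sum(axis=ax)
    return per_pixel.mean()


def adversarial_gate_perturbation(
        forward_fn: Callable[[list[Tensor]], Tensor],
        states: Sequence[GateState] | GateState,
        cfg: PerturbConfig,
        p_clean: Tensor | np.ndarray | None = None,
        rng: np.random.Generator | None = None) -> list[GateState]:
    """Projected sign-gradient ascent on the KL objective w.r.t. the gate(s).

    forward_fn maps a list of gate tensors (one per fusion site) to the
    predicted probability map; it must not create gradients into backbone
    parameters (the caller freezes them).  Returns states carrying the found
    perturbations; the clean gates are left untouched.

    The search starts from a small seeded random perturbation: the KL
    objective is exactly minimized (zero gradient) at the clean state, so a
    zero start would never move.
    """
    cfg.validate()
    single = isinstance(states, GateState)
    states = [states] if single else list(states)
    if cfg.epsilon == 0.0:
        out = [replace(s, perturbation=np.zeros_like(s.gate)) for s in states]
        return out[0] if single else out

    if p_clean is None:
        p_clean = forward_fn([Tensor(s.gate) for s in states])
    p_clean = Tensor(p_clean.data if isinstance(p_clean, Tensor) else p_clean)
    rng = rng if rng is not None else np.random.default_rng(0)
    deltas = [np.clip(1e-3 * rng.standard_normal(s.gate.shape),
                      -cfg.epsilon, cfg.epsilon).astype(np.float32)
              for s in states]
    step = cfg.effective_step
    for _ in range(cfg.n_steps):
        gate_ts = [Tensor(np.clip(s.gate + d, 0.0, 1.0), requires_grad=True)
                   for s, d in zip(states, deltas)]
        p_pert = forward_fn(gate_ts)
        kl_consistency(p_clean, p_pert).backward()
        for i, gt in enumerate(gate_ts):
            if gt.grad is None:
                continue
            deltas[i] = np.clip(deltas[i] + step * np.sign(gt.grad),
                                -cfg.epsilon, cfg.epsilon).astype(np.float32)
    out = [replace(s, perturbation=d) for s, d in zip(states, deltas)]
    return out[0] if single else out
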