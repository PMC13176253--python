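"""ATFiLM: consistency-regularized auxiliary-guided skip modulation.

Skip features s from the encoder are modulated channel-wise by an affine
transform whose parameters are inferred from the same-scale auxiliary
(generation-branch) feature a:

    s'[c] = gamma[c] * s[c] + beta[c],   (gamma, beta) = conditioner(pool(a))

with gamma parameterized as 1 + tanh(raw) so that a zero-initialized
conditioner is exactly the identity (a plain skip connection) — auxiliary
cues modulate, never override, the morphological content of the skip.  A
TRADES-style consistency term penalizes KL divergence between predictions
under clean and adversarially perturbed (gamma, beta); the perturbation is
bounded in infinity norm and never touches the skip features themselves.

Ablation modes: ``beta_only`` / ``gamma_only`` freeze the complementary
parameter at its identity value; ``concat`` replaces modulation by channel
concatenation + 1x1 projection (no consistency loss).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .gate import PerturbConfig, kl_consistency
from .nn import Conv2d, Linear, Module, Tensor, concat

__all__ = ["FiLMParams", "FiLMConditioner", "ConcatSkip", "infer_film_params",
           "film_modulate", "adversarial_film_perturbation", "film_consistency"]

FILM_MODES = ("full", "beta_only", "gamma_only", "concat", "off")


@dataclass
class FiLMParams:
    """Per-channel affine parameters, one row per batch sample."""

    gamma: np.ndarray | Tensor        # (B, C)
    beta: np.ndarray | Tensor         # (B, C)
    source: str = ""                  # identifier of the auxiliary feature

    def detached(self) -> "FiLMParams":
        g = self.gamma.numpy() if isinstance(self.gamma, Tensor) else self.gamma
        b = self.beta.numpy() if isinstance(self.beta, Tensor) else self.beta
        return FiLMParams(np.asarray(g), np.asarray(b), self.source)


class FiLMConditioner(Module):
    """pool(a) -> two-layer map -> (gamma_raw, beta); gamma = 1 + tanh(gamma_raw).

    ``mode`` freezes gamma ('beta_only') or beta ('gamma_only') at identity.
    """

    def __init__(self, c_aux: int, c_skip: int, *, mode: str = "full",
                 hidden: int | None = None, rng: np.random.Generator):
        if mode not in ("full", "beta_only", "gamma_only"):
            raise ValueError(f"unsupported conditioner mode: {mode}")
        self.mode = mode
        self.c_skip = c_skip
        hidden = hidden or max(c_aux // 2, 4)
        self.fc1 = Linear(c_aux, hidden, rng=rng)
        self.fc2 = Linear(hidden, 2 * c_skip, rng=rng)
        # identity fixed point: zero-init the output map
        self.fc2.weight.data[...] = 0.0
        self.fc2.bias.data[...] = 0.0

    def forward(self, a: Tensor, source: str = "") -> FiLMParams:
        b, c = a.shape[0], a.shape[1]
        pooled = a.mean(axis=(2, 3)).reshape(b, c)
        raw = self.fc2(self.fc1(pooled).relu())
        gamma = 1.0 + raw[:, :self.c_skip].tanh()
        beta = raw[:, self.c_skip:]
        if self.mode == "beta_only":
            gamma = Tensor(np.ones((b, self.c_skip), dtype=np.float32))
        elif self.mode == "gamma_only":
            beta = Tensor(np.zeros((b, self.c_skip), dtype=np.float32))
        return FiLMParams(gamma=gamma, beta=beta, source=source)


def infer_film_params(a: Tensor, conditioner: FiLMConditioner,
                      source: str = "") -> FiLMParams:
    """Functional alias for FiLMConditioner.forward."""
    return conditioner(a, source)


def film_modulate(s: Tensor, params: FiLMParams) -> Tensor:
    """s'[c] = gamma[c] * s[c] + beta[c], broadcast over space."""
    gamma = params.gamma if isinstance(params.gamma, Tensor) else Tensor(params.gamma)
    beta = params.beta if isinstance(params.beta, Tensor) else Tensor(params.beta)
    if gamma.shape[-1] != s.shape[1] or beta.shape[-1] != s.shape[1]:
        raise ValueError(
            f"FiLM parameter length {gamma.shape[-1]} does not match "
            f"skip channels {s.shape[1]}")
    b, c = s.shape[0], s.shape[1]
    return s * gamma.reshape(b, c, 1, 1) + beta.reshape(b, c, 1, 1)


class ConcatSkip(Module):
    """'Replaced with concatenation' ablation: [s ; a] -> 1x1 projection."""

    def __init__(self, c_skip: int, c_aux: int, *, rng: np.random.Generator):
        self.proj = Conv2d(c_skip + c_aux, c_skip, 1, rng=rng)

    def forward(self, s: Tensor, a: Tensor) -> Tensor:
        return self.proj(concat([s, a], axis=1))


def adversarial_film_perturbation(
        forward_fn: Callable[[list[FiLMParams]], Tensor],
        params: Sequence[FiLMParams] | FiLMParams,
        cfg: PerturbConfig,
        p_clean: Tensor | np.ndarray | None = None,
        rng: np.random.Generator | None = None) -> list[FiLMParams]:
    """Joint projected sign-gradient ascent on (gamma, beta) of every site.

    Returns perturbed FiLMParams (numpy-valued); the clean parameters and the
    skip features are untouched.  forward_fn maps a list of FiLMParams to a
    probability map; the caller freezes backbone parameters.  As for the gate
    search, a small seeded random start breaks the zero gradient of the KL
    objective at the clean state.
    """
    cfg.validate()
    single = isinstance(params, FiLMParams)
    params = [params] if single else list(params)
    clean = [p.detached() for p in params]
    if cfg.epsilon == 0.0:
        return clean[0] if single else clean

    if p_clean is None:
        p_clean = forward_fn([FiLMParams(Tensor(p.gamma), Tensor(p.beta), p.source)
                              for p in clean])
    p_clean = Tensor(p_clean.data if isinstance(p_clean, Tensor) else p_clean)
    rng = rng if rng is not None else np.random.default_rng(0)
    dg = [np.clip(1e-3 * rng.standard_normal(p.gamma.shape),
                  -cfg.epsilon, cfg.epsilon).astype(np.float32) for p in clean]
    db = [np.clip(1e-3 * rng.standard_normal(p.beta.shape),
                  -cfg.epsilon, cfg.epsilon).astype(np.float32) for p in clean]
    step = cfg.effective_step
    for _ in range(cfg.n_steps):
        g_ts = [Tensor(p.gamma + d, requires_grad=True) for p, d in zip(clean, dg)]
        b_ts = [Tensor(p.beta + d, requires_grad=True) for p, d in zip(clean, db)]
        p_pert = forward_fn([FiLMParams(g, b, p.source)
                             for g, b, p in zip(g_ts, b_ts, clean)])
        kl_consistency(p_clean, p_pert).backward()
        for i in range(len(clean)):
            if g_ts[i].grad is not None:
                dg[i] = np.clip(dg[i] + step * np.sign(g_ts[i].grad),
                                -cfg.epsilon, cfg.epsilon).astype(np.float32)
            if b_ts[i].grad is not None:
                db[i] = np.clip(db[i] + step * np.sign(b_ts[i].grad),
                                -cfg.epsilon, cfg.epsilon).astype(np.float32)
    out = [FiLMParams(p.gamma + g, p.beta + b, p.source)
           for p, g, b in zip(clean, dg, db)]
    return out[0] if single else out


def film_consistency(p_clean, p_pert) -> Tensor:
    """KL( p(s') || p(s~') ): identical contract to the gate consistency."""
    return kl_consistency(p_clean, p_pert)
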