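"""Layer modules on top of the autodiff core: parameter registry, conv, linear,
instance normalization, and (de)serialization of parameter state."""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

from .autodiff import Tensor, conv2d, instance_norm_affine


class Module:
    """Base class: child modules and parameters are discovered by attribute walk."""

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(full)
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{full}.{i}", item

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name], dtype=np.float32).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


@contextmanager
def frozen(params: list[Tensor]):
    """Temporarily exclude parameters from the autodiff graph (no grad, no cost)."""
    prev = [p.requires_grad for p in params]
    for p in params:
        p.requires_grad = False
        p._needs_grad = False
    try:
        yield
    finally:
        for p, r in zip(params, prev):
            p.requires_grad = r
            p._needs_grad = r


def _he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Module):
    """Same-padded by default; supports stride and dilation."""

    def __init__(self, c_in: int, c_out: int, kernel_size: int = 3, *,
                 stride: int = 1, dilation: int = 1, padding: str | int = "same",
                 bias: bool = True, rng: np.random.Generator):
        if dilation < 1:
            raise ValueError("dilation must be >= 1")
        k = kernel_size
        if padding == "same":
            if stride != 1:
                raise ValueError("'same' padding requires stride 1")
            padding = ((k - 1) * dilation) // 2
        self.stride = stride
        self.dilation = dilation
        self.padding = int(padding)
        self.weight = Tensor(_he_normal(rng, (c_out, c_in, k, k), c_in * k * k),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      dilation=self.dilation, padding=self.padding)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, *, bias: bool = True,
                 rng: np.random.Generator):
        self.weight = Tensor(_he_normal(rng, (n_in, n_out), n_in), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalization with learned affine; batch-size robust."""

    def __init__(self, c: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Tensor(np.ones((1, c, 1, 1), dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros((1, c, 1, 1), dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return instance_norm_affine(x, self.gamma, self.beta, self.eps)


class ConvNormAct(Module):
    """conv -> instance norm -> rectifier, the package's standard unit."""

    def __init__(self, c_in: int, c_out: int, kernel_size: int = 3, *,
                 stride: int = 1, dilation: int = 1, rng: np.random.Generator):
        pad = "same" if stride == 1 else (kernel_size - 1) // 2
        self.conv = Conv2d(c_in, c_out, kernel_size, stride=stride,
                           dilation=dilation, padding=pad, rng=rng)
        self.norm = InstanceNorm2d(c_out)

    def forward(self, x: Tensor) -> Tensor:
        return self.norm(self.conv(x)).relu()
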