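"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tensor/graph core: just the operations the package's
convolutional architecture needs (dense/dilated/strided convolution, pointwise
arithmetic, reductions, logistic/tanh/rectifier nonlinearities, log-softmax,
nearest-neighbor upsampling, channel concat/slice, clamping).  Float32
throughout; gradients are accumulated into ``.grad`` of every node that
requires them.  The graph is pruned at construction time: an operation whose
inputs are all constants produces a constant, so freezing parameters
(``requires_grad = False``) removes them from the backward pass entirely.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "tensor", "concat", "conv2d", "upsample_nearest2x"]

_F32 = np.float32


def _as_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=_F32)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading broadcast axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over size-1 axes
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional backward graph."""

    __slots__ = ("data", "grad", "requires_grad", "_needs_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._needs_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p._needs_grad for p in parents):
            out._needs_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self):
        self.grad = None

    # -- autograd -------------------------------------------------------------
    def backward(self, grad=None):
        if not self._needs_grad:
            return
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node._needs_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = _as_array(grad) if self.grad is None else self.grad + _as_array(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray):
        if not self._needs_grad:
            return
        if self.grad is None:
            self.grad = g.astype(_F32, copy=True)
        else:
            self.grad += g

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = _wrap(other)
        out_data = self.data + other.data

        def bw(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-_wrap(other))

    def __rsub__(self, other):
        return _wrap(other) + (-self)

    def __mul__(self, other):
        other = _wrap(other)
        out_data = self.data * other.data

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _wrap(other)
        out_data = self.data / other.data

        def bw(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(_unbroadcast(-g * self.data / (other.data ** 2), other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    def __rtruediv__(self, other):
        return _wrap(other) / self

    def __pow__(self, p: float):
        out_data = self.data ** p

        def bw(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(out_data, (self,), bw)

    def __matmul__(self, other):
        other = _wrap(other)
        out_data = self.data @ other.data

        def bw(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        return Tensor._make(out_data, (self, other), bw)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bw(g):
            # basic (slice) indexing only: no duplicate positions to worry about
            full = np.zeros_like(self.data)
            full[idx] += g
            self._accum(full)

        return Tensor._make(out_data, (self,), bw)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g):
            self._accum(g * (0.5 / out_data))

        return Tensor._make(out_data, (self,), bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            self._accum(g * (1.0 - out_data ** 2))

        return Tensor._make(out_data, (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), bw)

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        scale = np.where(mask, _F32(1.0), _F32(slope))

        def bw(g):
            self._accum(g * scale)

        return Tensor._make(self.data * scale, (self,), bw)

    def abs(self):
        sign = np.sign(self.data)

        def bw(g):
            self._accum(g * sign)

        return Tensor._make(np.abs(self.data), (self,), bw)

    def clamp(self, lo: float, hi: float):
        """Clamp values; gradient passes only through the interior."""
        mask = (self.data >= lo) & (self.data <= hi)

        def bw(g):
            self._accum(g * mask)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), bw)

    # -- reductions & shape ---------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).astype(_F32))

        return Tensor._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape

        def bw(g):
            self._accum(g.reshape(orig))

        return Tensor._make(self.data.reshape(shape), (self,), bw)

    def log_softmax(self, axis: int = 1):
        m = self.data.max(axis=axis, keepdims=True)
        z = self.data - m
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        out_data = z - lse
        soft = np.exp(out_data)

        def bw(g):
            self._accum(g - soft * g.sum(axis=axis, keepdims=True))

        return Tensor._make(out_data, (self,), bw)

    def softmax(self, axis: int = 1):
        return self.log_softmax(axis=axis).exp()

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accum(g[tuple(idx)])

    return Tensor._make(out_data, tuple(tensors), bw)


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int, dilation: int):
    """Extract convolution patches from a padded (B,C,H,W) array.

    Returns (B, L, C*kh*kw) with L = Hout*Wout, plus the output spatial size.
    """
    eff_kh = (kh - 1) * dilation + 1
    eff_kw = (kw - 1) * dilation + 1
    win = sliding_window_view(xp, (eff_kh, eff_kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride, ::dilation, ::dilation]
    b, c, ho, wo = win.shape[:4]
    col = win.transpose(0, 2, 3, 1, 4, 5).reshape(b, ho * wo, c * kh * kw)
    return np.ascontiguousarray(col), ho, wo


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           dilation: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation) on (B,C,H,W) with (O,C,kh,kw) weights."""
    B, C, H, W = x.data.shape
    O, Cw, kh, kw = w.data.shape
    if C != Cw:
        raise ValueError(f"conv2d channel mismatch: input has {C}, weight expects {Cw}")
    if stride < 1 or dilation < 1:
        raise ValueError("stride and dilation must be >= 1")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
        if padding else x.data
    col, ho, wo = _im2col(xp, kh, kw, stride, dilation)
    wmat = w.data.reshape(O, C * kh * kw)
    out = col @ wmat.T                      # (B, L, O)
    if b is not None:
        out = out + b.data[None, None, :]
    out_data = out.transpose(0, 2, 1).reshape(B, O, ho, wo)

    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        g_blo = g.reshape(B, O, ho * wo).transpose(0, 2, 1)     # (B, L, O)
        if b is not None:
            b._accum(g_blo.sum(axis=(0, 1)))
        if w._needs_grad:
            dw = np.tensordot(g_blo, col, axes=([0, 1], [0, 1]))  # (O, C*kh*kw)
            w._accum(dw.reshape(O, C, kh, kw))
        if x._needs_grad:
            dcol = g_blo @ wmat                                  # (B, L, C*kh*kw)
            dcol = dcol.reshape(B, ho, wo, C, kh, kw).transpose(0, 3, 4, 5, 1, 2)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                hi = i * dilation
                for j in range(kw):
                    wj = j * dilation
                    dxp[:, :, hi:hi + stride * ho:stride,
                        wj:wj + stride * wo:stride] += dcol[:, :, i, j]
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accum(dxp)

    return Tensor._make(out_data, parents, bw)


def instance_norm_affine(x: Tensor, gamma: Tensor, beta: Tensor,
                         eps: float = 1e-5) -> Tensor:
    """Fused per-sample per-channel normalization with affine parameters
    (gamma, beta shaped (1,C,1,1)); one primitive instead of an op chain."""
    mu = x.data.mean(axis=(2, 3), keepdims=True)
    centered = x.data - mu
    var = (centered ** 2).mean(axis=(2, 3), keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = centered * inv_std
    out_data = xhat * gamma.data + beta.data

    def bw(g):
        if beta._needs_grad:
            beta._accum(g.sum(axis=(0, 2, 3), keepdims=True))
        if gamma._needs_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3), keepdims=True))
        if x._needs_grad:
            gx = g * gamma.data
            m1 = gx.mean(axis=(2, 3), keepdims=True)
            m2 = (gx * xhat).mean(axis=(2, 3), keepdims=True)
            x._accum((gx - m1 - xhat * m2) * inv_std)

    return Tensor._make(out_data, (x, gamma, beta), bw)


def upsample_nearest2x(x: Tensor) -> Tensor:
    out_data = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def bw(g):
        B, C, H2, W2 = g.shape
        x._accum(g.reshape(B, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5)))

    return Tensor._make(out_data, (x,), bw)
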