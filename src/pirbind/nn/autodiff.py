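"""Minimal tape-based reverse-mode automatic differentiation on NumPy.

Just enough machinery for the attention classifier: broadcast-aware
elementwise arithmetic, (batched) matmul, reshaping/concatenation,
reductions, the activations used by the model, and a sliding-window unfold
primitive that expresses 1D convolution as a matrix product.  All arrays are
float32; gradients accumulate in float32 as well.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def param(data) -> "Tensor":
        return Tensor(np.asarray(data, dtype=np.float32), requires_grad=True)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autodiff core -------------------------------------------------------
    def backward(self, grad: "np.ndarray | None" = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if not self.requires_grad and self._backward is None:
            return
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad = self.grad + grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- operations ----------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor(self.data + other.data, parents=(self, other), backward=bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accumulate(-g)

        return Tensor(-self.data, parents=(self,), backward=bw)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(self.data * other.data, parents=(self, other), backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
            )

        return Tensor(self.data / other.data, parents=(self, other), backward=bw)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = self.data @ other.data

        def bw(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            self._accumulate(_unbroadcast(ga, self.data.shape))
            other._accumulate(_unbroadcast(gb, other.data.shape))

        return Tensor(out, parents=(self, other), backward=bw)

    def pow(self, exponent: float):
        def bw(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor(self.data**exponent, parents=(self,), backward=bw)

    def sqrt(self):
        out = np.sqrt(self.data)

        def bw(g):
            self._accumulate(g * 0.5 / np.maximum(out, 1e-12))

        return Tensor(out, parents=(self,), backward=bw)

    def exp(self):
        out = np.exp(self.data)

        def bw(g):
            self._accumulate(g * out)

        return Tensor(out, parents=(self,), backward=bw)

    def log(self):
        def bw(g):
            self._accumulate(g / self.data)

        return Tensor(np.log(self.data), parents=(self,), backward=bw)

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accumulate(g * out * (1.0 - out))

        return Tensor(out, parents=(self,), backward=bw)

    def relu(self):
        mask = (self.data > 0).astype(np.float32)

        def bw(g):
            self._accumulate(g * mask)

        return Tensor(self.data * mask, parents=(self,), backward=bw)

    def reshape(self, *shape):
        old = self.data.shape

        def bw(g):
            self._accumulate(g.reshape(old))

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=bw)

    def mT(self):
        """Swap the last two axes."""

        def bw(g):
            self._accumulate(np.swapaxes(g, -1, -2))

        return Tensor(np.swapaxes(self.data, -1, -2), parents=(self,), backward=bw)

    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                for ax in sorted(a % self.data.ndim for a in axes):
                    gg = np.expand_dims(gg, ax)
            self._accumulate(np.broadcast_to(gg, self.data.shape).astype(np.float32))

        return Tensor(out, parents=(self,), backward=bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            denom = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            denom = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / denom)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accumulate(g[tuple(idx)])

    return Tensor(out, parents=tuple(tensors), backward=bw)


def prelu(x: Tensor, alpha: Tensor) -> Tensor:
    """Parametric ReLU with a (broadcastable, typically per-channel) slope."""
    pos = (x.data > 0).astype(np.float32)
    neg = 1.0 - pos
    out = x.data * pos + alpha.data * x.data * neg

    def bw(g):
        x._accumulate(g * (pos + alpha.data * neg))
        alpha._accumulate(_unbroadcast(g * x.data * neg, alpha.data.shape))

    return Tensor(out, parents=(x, alpha), backward=bw)


def unfold(x: Tensor, window: int, pad: int) -> Tensor:
    """Zero-pad the length axis of a (B, L, C) tensor and stack sliding
    windows: output (B, L_out, window*C) with L_out = L + 2*pad - window + 1.

    With ``pad = (window - 1) // 2`` this gives the same-length im2col layout
    used to express 1D convolution as a single matrix product.
    """
    B, L, C = x.data.shape
    padded = np.zeros((B, L + 2 * pad, C), dtype=np.float32)
    padded[:, pad : pad + L, :] = x.data
    L_out = L + 2 * pad - window + 1
    view = np.lib.stride_tricks.sliding_window_view(padded, window, axis=1)
    # view: (B, L_out, C, window) -> (B, L_out, window, C)
    out = np.ascontiguousarray(view.transpose(0, 1, 3, 2)).reshape(B, L_out, window * C)

    def bw(g):
        gp = np.zeros_like(padded)
        gw = g.reshape(B, L_out, window, C)
        for w in range(window):
            gp[:, w : w + L_out, :] += gw[:, :, w, :]
        x._accumulate(gp[:, pad : pad + L, :])

    return Tensor(out, parents=(x,), backward=bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        dot = (g * out).sum(axis=axis, keepdims=True)
        x._accumulate(out * (g - dot))

    return Tensor(out, parents=(x,), backward=bw)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out = shifted - lse
    soft = np.exp(out)

    def bw(g):
        x._accumulate(g - soft * g.sum(axis=axis, keepdims=True))

    return Tensor(out, parents=(x,), backward=bw)


def dropout(x: Tensor, p: float, rng: np.random.Generator, train: bool) -> Tensor:
    if not train or p <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p).astype(np.float32) / (1.0 - p)

    def bw(g):
        x._accumulate(g * mask)

    return Tensor(x.data * mask, parents=(x,), backward=bw)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize over the last axis, then scale and shift."""
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    xn = xc / (var + eps).sqrt()
    return xn * gamma + beta


class BatchNorm:
    """Batch normalization over all axes except the trailing channel axis.

    Training mode normalizes with batch statistics (differentiably) and
    updates running estimates (momentum 0.1); eval mode applies the affine
    transform with the stored running statistics.
    """

    def __init__(self, n_channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor.param(np.ones(n_channels))
        self.beta = Tensor.param(np.zeros(n_channels))
        self.running_mean = np.zeros(n_channels, dtype=np.float32)
        self.running_var = np.ones(n_channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        axes = tuple(range(x.ndim - 1))
        if train:
            mu = x.mean(axis=axes, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=axes, keepdims=True)
            xn = xc / (var + self.eps).sqrt()
            n = int(np.prod([x.shape[a] for a in axes]))
            unbiased = var.data.reshape(-1) * (n / max(n - 1, 1))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean
                + self.momentum * mu.data.reshape(-1)
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * unbiased
            )
            return xn * self.gamma + self.beta
        scale = self.gamma.data / np.sqrt(self.running_var + self.eps)
        shift = self.beta.data - self.running_mean * scale
        return x * Tensor(scale) + Tensor(shift)

    def parameters(self) -> list[Tensor]:
        return [self.gamma, self.beta]

    def state(self) -> dict[str, np.ndarray]:
        return {"running_mean": self.running_mean, "running_var": self.running_var}
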