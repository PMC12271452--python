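"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the encoder stack needs: broadcasted
arithmetic, batched matrix products, softmax/log-softmax, embedding lookup,
pairwise gather (for relative-position attention), reductions, tanh/GELU and
the two classification losses.  Gradients are accumulated by topological
traversal of the recorded computation graph; broadcast gradients are reduced
back to the parameter's shape.  The engine is validated against central
finite differences in the test suite.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[], None] | None = None
        self._prev: tuple[Tensor, ...] = ()

    # -- graph bookkeeping -------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"]) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        out._prev = tuple(p for p in parents if p.requires_grad)
        return out

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor._make(self.data + other.data, (self, other))

        def bw():
            if self.requires_grad:
                self._accum(out.grad)
            if other.requires_grad:
                other._accum(out.grad)

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor._make(-self.data, (self,))
        out._backward = lambda: self.requires_grad and self._accum(-out.grad)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor._make(self.data * other.data, (self, other))

        def bw():
            if self.requires_grad:
                self._accum(out.grad * other.data)
            if other.requires_grad:
                other._accum(out.grad * self.data)

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor._make(self.data ** p, (self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad * p * self.data ** (p - 1.0))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor._make(self.data @ other.data, (self, other))

        def bw():
            if self.requires_grad:
                self._accum(out.grad @ np.swapaxes(other.data, -1, -2))
            if other.requires_grad:
                other._accum(np.swapaxes(self.data, -1, -2) @ out.grad)

        out._backward = bw
        return out

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        orig = self.data.shape
        out = Tensor._make(self.data.reshape(*shape), (self,))
        out._backward = lambda: self.requires_grad and self._accum(out.grad.reshape(orig))
        return out

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)
        out = Tensor._make(self.data.transpose(axes), (self,))
        out._backward = lambda: self.requires_grad and self._accum(out.grad.transpose(inv))
        return out

    def swapaxes(self, a: int, b: int):
        out = Tensor._make(np.swapaxes(self.data, a, b), (self,))
        out._backward = lambda: self.requires_grad and self._accum(np.swapaxes(out.grad, a, b))
        return out

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw():
            if not self.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities ----------------------------------------
    def exp(self):
        out = Tensor._make(np.exp(self.data), (self,))
        out._backward = lambda: self.requires_grad and self._accum(out.grad * out.data)
        return out

    def log(self):
        out = Tensor._make(np.log(self.data), (self,))
        out._backward = lambda: self.requires_grad and self._accum(out.grad / self.data)
        return out

    def tanh(self):
        out = Tensor._make(np.tanh(self.data), (self,))
        out._backward = lambda: self.requires_grad and self._accum(out.grad * (1.0 - out.data ** 2))
        return out

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()


# ---------------------------------------------------------------------------
# Composite / dedicated operations


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    s = np.exp(shifted)
    s /= s.sum(axis=axis, keepdims=True)
    out = Tensor._make(s, (x,))

    def bw():
        if x.requires_grad:
            g = out.grad
            x._accum(s * (g - (g * s).sum(axis=axis, keepdims=True)))

    out._backward = bw
    return out


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    ls = shifted - lse
    out = Tensor._make(ls, (x,))

    def bw():
        if x.requires_grad:
            g = out.grad
            x._accum(g - np.exp(ls) * g.sum(axis=axis, keepdims=True))

    out._backward = bw
    return out


def gelu(x: Tensor) -> Tensor:
    """GELU with the tanh approximation (differentiated through the graph)."""
    c = math.sqrt(2.0 / math.pi)
    inner = (x + x * x * x * 0.044715) * c
    return x * 0.5 * (inner.tanh() + 1.0)


def embedding(weight: Tensor, idx: np.ndarray) -> Tensor:
    """Row lookup ``weight[idx]`` with scatter-add backward."""
    idx = np.asarray(idx)
    out = Tensor._make(weight.data[idx], (weight,))

    def bw():
        if weight.requires_grad:
            g = np.zeros_like(weight.data)
            np.add.at(g, idx.reshape(-1), out.grad.reshape(-1, weight.data.shape[-1]))
            weight._accum(g)

    out._backward = bw
    return out


def gather_last(x: Tensor, index: np.ndarray) -> Tensor:
    """``out[..., i, j] = x[..., i, index[i, j]]`` for relative-position lookups.

    ``x`` has shape (..., L, R) and ``index`` shape (L, L) with entries in
    [0, R); the result has shape (..., L, L).
    """
    index = np.asarray(index)
    idx_b = np.broadcast_to(index, x.data.shape[:-1] + index.shape[-1:])
    out_data = np.take_along_axis(x.data, idx_b, axis=-1)
    out = Tensor._make(out_data, (x,))

    def bw():
        if x.requires_grad:
            g = np.zeros_like(x.data)
            flat_g = g.reshape(-1, g.shape[-1])
            flat_out = out.grad.reshape(-1, out.grad.shape[-1])
            flat_idx = np.broadcast_to(index, out.grad.shape).reshape(-1, out.grad.shape[-1])
            rows = np.repeat(np.arange(flat_g.shape[0]), flat_idx.shape[1])
            np.add.at(flat_g, (rows, flat_idx.reshape(-1)), flat_out.reshape(-1))
            x._accum(g)

    out._backward = bw
    return out


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-6) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    centred = x - mu
    var = (centred * centred).mean(axis=-1, keepdims=True)
    return centred * ((var + eps) ** -0.5) * gain + bias


def cross_entropy(logits: Tensor, targets: np.ndarray, weights: np.ndarray | None = None) -> Tensor:
    """Mean (optionally weighted) negative log-likelihood over rows of logits."""
    targets = np.asarray(targets, dtype=np.int64)
    n, _ = logits.data.shape
    ls = log_softmax(logits, axis=-1)
    onehot = np.zeros_like(logits.data)
    onehot[np.arange(n), targets] = 1.0
    if weights is None:
        return -(ls * onehot).sum() * (1.0 / max(n, 1))
    w = np.asarray(weights, dtype=np.float64)
    total = max(w.sum(), 1e-12)
    return -(ls * (onehot * w[:, None])).sum() * (1.0 / total)


def binary_cross_entropy_with_logits(
    logits: Tensor, targets: np.ndarray, weights: np.ndarray | None = None
) -> Tensor:
    """Numerically stable mean BCE; ``weights`` masks/weights each element."""
    t = np.asarray(targets, dtype=np.float64)
    x = logits
    # log(1 + exp(-|x|)) + max(x, 0) - x * t
    absx = Tensor._make(np.abs(x.data), (x,))
    absx._backward = lambda: x.requires_grad and x._accum(absx.grad * np.sign(x.data))
    relu = Tensor._make(np.maximum(x.data, 0.0), (x,))
    relu._backward = lambda: x.requires_grad and x._accum(relu.grad * (x.data > 0))
    loss = ((-absx).exp() + 1.0).log() + relu - x * t
    if weights is None:
        return loss.mean()
    w = np.asarray(weights, dtype=np.float64)
    total = max(w.sum(), 1e-12)
    return (loss * w).sum() * (1.0 / total)


def dropout(x: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity when ``rng`` is None (evaluation mode)."""
    if rng is None or rate <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)


# ---------------------------------------------------------------------------
# Parameters and optimisation


def parameter(rng: np.random.Generator, *shape: int, scale: float | None = None) -> Tensor:
    """Gaussian-initialised trainable tensor (scale defaults to 0.02)."""
    scale = 0.02 if scale is None else scale
    t = Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)
    return t


def zeros(*shape: int) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


def ones(*shape: int) -> Tensor:
    return Tensor(np.ones(shape), requires_grad=True)


class Adam:
    """Adam optimiser over an explicit parameter list."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
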