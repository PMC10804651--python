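"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the sequence models need: broadcasting
arithmetic, (batched) matmul, elementwise nonlinearities, reductions,
basic-slice indexing, stacking, embedding lookup and gather along the
last axis.  Gradients are accumulated in float64; graphs are built per
forward pass and freed after ``backward``.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "constant",
    "parameter",
    "stack",
    "embedding",
    "gather_last",
    "log_softmax",
    "softmax",
    "Adam",
    "clip_global_norm",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers ------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- autodiff core -------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        order: list[Tensor] = []
        seen: set[int] = set()
        stack_: list[tuple[Tensor, bool]] = [(self, False)]
        while stack_:
            node, processed = stack_.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack_.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack_.append((p, False))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free graph references as we go
            if node is not self:
                node._backward = None
                node._parents = ()

    # -- operators -----------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        out = _op(np.add(self.data, other.data), self, other)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _op(-self.data, self)

        def bw(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = _op(self.data * other.data, self, other)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return _as_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        exponent = float(exponent)
        out = _op(self.data ** exponent, self)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = _op(np.matmul(self.data, other.data), self, other)

        def bw(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accumulate(_unbroadcast(gb, other.shape))

        out._backward = bw
        return out

    # -- elementwise ---------------------------------------------------------

    def exp(self):
        out = _op(np.exp(self.data), self)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * out.data)

        out._backward = bw
        return out

    def log(self):
        out = _op(np.log(self.data), self)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = bw
        return out

    def tanh(self):
        out = _op(np.tanh(self.data), self)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - out.data ** 2))

        out._backward = bw
        return out

    def sigmoid(self):
        out = _op(1.0 / (1.0 + np.exp(-self.data)), self)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * out.data * (1.0 - out.data))

        out._backward = bw
        return out

    def relu(self):
        out = _op(np.maximum(self.data, 0.0), self)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * (self.data > 0.0))

        out._backward = bw
        return out

    def sqrt(self):
        return self ** 0.5

    # -- reductions / shaping ------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = _op(self.data.sum(axis=axis, keepdims=keepdims), self)

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _op(self.data.reshape(shape), self)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.shape))

        out._backward = bw
        return out

    def transpose(self, axes: Sequence[int]):
        axes = tuple(axes)
        out = _op(np.transpose(self.data, axes), self)
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accumulate(np.transpose(g, inv))

        out._backward = bw
        return out

    def swapaxes(self, a: int, b: int):
        out = _op(np.swapaxes(self.data, a, b), self)

        def bw(g):
            if self.requires_grad:
                self._accumulate(np.swapaxes(g, a, b))

        out._backward = bw
        return out

    def __getitem__(self, key):
        out = _op(self.data[key], self)

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[key] += g  # basic slicing only: no aliasing
                self._accumulate(full)

        out._backward = bw
        return out

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _op(data: np.ndarray, *parents: Tensor) -> Tensor:
    out = Tensor(data)
    tracked = tuple(p for p in parents if p.requires_grad or p._parents)
    out._parents = tracked
    out.requires_grad = any(p.requires_grad for p in parents)
    return out


def constant(data) -> Tensor:
    return Tensor(data)


def parameter(data, rng: np.random.Generator | None = None) -> Tensor:
    return Tensor(data, requires_grad=True)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out = _op(np.stack([t.data for t in tensors], axis=axis), *tensors)

    def bw(g):
        pieces = np.split(g, len(tensors), axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accumulate(np.squeeze(piece, axis=axis))

    out._backward = bw
    return out


def embedding(weight: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup ``weight[ids]`` with scatter-add backward."""
    ids = np.asarray(ids)
    out = _op(weight.data[ids], weight)

    def bw(g):
        if weight.requires_grad:
            full = np.zeros_like(weight.data)
            np.add.at(full, ids.reshape(-1), g.reshape(-1, weight.data.shape[-1]))
            weight._accumulate(full)

    out._backward = bw
    return out


def gather_last(x: Tensor, idx: np.ndarray) -> Tensor:
    """Pick ``x[..., idx]`` elementwise along the last axis; idx shape = x.shape[:-1]."""
    idx = np.asarray(idx)
    out = _op(np.take_along_axis(x.data, idx[..., None], axis=-1)[..., 0], x)

    def bw(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            np.put_along_axis(full, idx[..., None], g[..., None], axis=-1)
            x._accumulate(full)

    out._backward = bw
    return out


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable log-softmax; the max shift is treated as a constant."""
    m = constant(np.max(x.data, axis=axis, keepdims=True))
    z = x - m
    lse = z.exp().sum(axis=axis, keepdims=True).log()
    return z - lse


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = constant(np.max(x.data, axis=axis, keepdims=True))
    e = (x - m).exp()
    return e / e.sum(axis=axis, keepdims=True)


def clip_global_norm(params: Iterable[Tensor], max_norm: float) -> float:
    """Scale all gradients so their joint L2 norm is at most ``max_norm``."""
    params = [p for p in params if p.grad is not None]
    total = float(np.sqrt(sum(float((p.grad ** 2).sum()) for p in params)))
    if total > max_norm > 0.0:
        scale = max_norm / (total + 1e-12)
        for p in params:
            p.grad *= scale
    return total


class Adam:
    """Adam optimizer (Kingma & Ba) with bias correction."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
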