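"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The model in this package is small (tens of parameters tensors, molecular
graphs with tens of atoms), so a lightweight tape-based engine is sufficient:
every operation builds a node holding its inputs and a closure that
distributes the incoming gradient.  Broadcasting follows NumPy semantics;
gradients of broadcast operands are summed back to the operand's shape.

Only the operations the model needs are provided: elementwise arithmetic,
(batched) matrix products, reductions, the usual nonlinearities, and the two
graph primitives ``gather`` (row indexing) and ``segment_sum`` (scatter-add
of rows into buckets), which express message passing over directed bonds.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Var",
    "as_var",
    "gather",
    "segment_sum",
    "stack",
    "concat",
    "softmax",
    "segment_softmax",
    "glorot",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away leading dims
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over dims that were broadcast from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Var:
    """A node in the computation tape: an ndarray plus gradient plumbing."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Var", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover
        return f"Var(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- gradient accumulation -------------------------------------------

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node (default seed: ones)."""
        if not self.requires_grad:
            raise RuntimeError("backward() on a node that requires no grad")
        topo: list[Var] = []
        seen: set[int] = set()
        stack_: list[tuple[Var, bool]] = [(self, False)]
        while stack_:  # iterative topological sort; graphs can be deep
            node, processed = stack_.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack_.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack_.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other) -> "Var":
        other = as_var(other)
        out_data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Var(out_data, _parents=(self, other), _backward=bw)

    __radd__ = __add__

    def __mul__(self, other) -> "Var":
        other = as_var(other)
        out_data = self.data * other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Var(out_data, _parents=(self, other), _backward=bw)

    __rmul__ = __mul__

    def __neg__(self) -> "Var":
        return self * (-1.0)

    def __sub__(self, other) -> "Var":
        return self + (-as_var(other))

    def __rsub__(self, other) -> "Var":
        return as_var(other) + (-self)

    def __truediv__(self, other) -> "Var":
        other = as_var(other)
        return self * other ** (-1.0)

    def __rtruediv__(self, other) -> "Var":
        return as_var(other) * self ** (-1.0)

    def __pow__(self, p: float) -> "Var":
        out_data = self.data**p

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1.0))

        return Var(out_data, _parents=(self,), _backward=bw)

    def __matmul__(self, other) -> "Var":
        other = as_var(other)
        out_data = np.matmul(self.data, other.data)

        def bw(g):
            a, b = self.data, other.data
            # promote 1-D operands so the transpose rule applies uniformly
            a2 = a[None, :] if a.ndim == 1 else a
            b2 = b[:, None] if b.ndim == 1 else b
            g2 = np.asarray(g, dtype=np.float64)
            if a.ndim == 1 and b.ndim == 1:
                g2 = g2.reshape(1, 1)
            elif a.ndim == 1:
                g2 = np.expand_dims(g2, -2)
            elif b.ndim == 1:
                g2 = np.expand_dims(g2, -1)
            if self.requires_grad:
                ga = np.matmul(g2, np.swapaxes(b2, -1, -2))
                if a.ndim == 1:
                    ga = ga[..., 0, :]
                self._accumulate(_unbroadcast(ga, a.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(a2, -1, -2), g2)
                if b.ndim == 1:
                    gb = gb[..., 0]
                other._accumulate(_unbroadcast(gb, b.shape))

        return Var(out_data, _parents=(self, other), _backward=bw)

    # -- reductions and shaping ------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Var":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        return Var(out_data, _parents=(self,), _backward=bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Var":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Var":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        orig = self.data.shape

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(orig))

        return Var(out_data, _parents=(self,), _backward=bw)

    def swapaxes(self, a1: int, a2: int) -> "Var":
        out_data = np.swapaxes(self.data, a1, a2)

        def bw(g):
            if self.requires_grad:
                self._accumulate(np.swapaxes(g, a1, a2))

        return Var(out_data, _parents=(self,), _backward=bw)

    @property
    def T(self) -> "Var":
        return self.swapaxes(-1, -2)

    # -- nonlinearities ---------------------------------------------------

    def relu(self) -> "Var":
        mask = self.data > 0
        out_data = self.data * mask

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Var(out_data, _parents=(self,), _backward=bw)

    def tanh(self) -> "Var":
        out_data = np.tanh(self.data)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - out_data**2))

        return Var(out_data, _parents=(self,), _backward=bw)

    def exp(self) -> "Var":
        out_data = np.exp(self.data)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return Var(out_data, _parents=(self,), _backward=bw)

    def log(self) -> "Var":
        out_data = np.log(self.data)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Var(out_data, _parents=(self,), _backward=bw)

    def sigmoid(self) -> "Var":
        # numerically stable logistic
        out_data = np.empty_like(self.data)
        pos = self.data >= 0
        out_data[pos] = 1.0 / (1.0 + np.exp(-self.data[pos]))
        ex = np.exp(self.data[~pos])
        out_data[~pos] = ex / (1.0 + ex)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return Var(out_data, _parents=(self,), _backward=bw)

    def clip(self, lo: float, hi: float) -> "Var":
        """Clamp values; gradient passes through only inside [lo, hi]."""
        mask = (self.data >= lo) & (self.data <= hi)
        out_data = np.clip(self.data, lo, hi)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Var(out_data, _parents=(self,), _backward=bw)


def as_var(x) -> Var:
    return x if isinstance(x, Var) else Var(x)


# -- graph primitives -----------------------------------------------------


def gather(x: Var, idx: np.ndarray) -> Var:
    """Row indexing ``x[idx]`` along axis 0 with scatter-add backward."""
    idx = np.asarray(idx, dtype=np.intp)
    out_data = x.data[idx]

    def bw(g):
        if x.requires_grad:
            acc = np.zeros_like(x.data)
            np.add.at(acc, idx, g)
            x._accumulate(acc)

    return Var(out_data, _parents=(x,), _backward=bw)


def segment_sum(x: Var, idx: np.ndarray, n: int) -> Var:
    """Sum rows of ``x`` into ``n`` buckets: ``out[i] = sum over idx==i``."""
    idx = np.asarray(idx, dtype=np.intp)
    out_data = np.zeros((n,) + x.data.shape[1:], dtype=np.float64)
    np.add.at(out_data, idx, x.data)

    def bw(g):
        if x.requires_grad:
            x._accumulate(g[idx])

    return Var(out_data, _parents=(x,), _backward=bw)


def stack(vars_: Sequence[Var], axis: int = 0) -> Var:
    vars_ = [as_var(v) for v in vars_]
    out_data = np.stack([v.data for v in vars_], axis=axis)

    def bw(g):
        pieces = np.split(g, len(vars_), axis=axis)
        for v, piece in zip(vars_, pieces):
            if v.requires_grad:
                v._accumulate(piece.reshape(v.data.shape))

    return Var(out_data, _parents=tuple(vars_), _backward=bw)


def concat(vars_: Sequence[Var], axis: int = 0) -> Var:
    vars_ = [as_var(v) for v in vars_]
    out_data = np.concatenate([v.data for v in vars_], axis=axis)
    sizes = [v.data.shape[axis] for v in vars_]

    def bw(g):
        splits = np.cumsum(sizes)[:-1]
        for v, piece in zip(vars_, np.split(g, splits, axis=axis)):
            if v.requires_grad:
                v._accumulate(piece)

    return Var(out_data, _parents=tuple(vars_), _backward=bw)


def softmax(x: Var, axis: int = -1) -> Var:
    """Numerically stable softmax; the shift is treated as a constant."""
    shift = Var(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def segment_softmax(scores: Var, idx: np.ndarray, n: int) -> Var:
    """Softmax of ``scores`` (1-D) within each bucket given by ``idx``."""
    idx = np.asarray(idx, dtype=np.intp)
    shift = np.full(n, -np.inf)
    np.maximum.at(shift, idx, scores.data)
    shift[~np.isfinite(shift)] = 0.0  # empty buckets
    e = (scores - Var(shift[idx])).exp()
    denom = segment_sum(e, idx, n)
    return e / gather(denom, idx)


# -- parameters and optimization ------------------------------------------


def glorot(rng: np.random.Generator, *shape: int) -> Var:
    """Glorot/Xavier-uniform initialized trainable tensor."""
    if len(shape) == 1:
        fan_in = fan_out = shape[0]
    else:
        fan_in, fan_out = shape[-1], shape[-2]
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return Var(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Adam:
    """Adam with optional L2 weight decay added to the gradient."""

    def __init__(self, params: Sequence[Var], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)
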