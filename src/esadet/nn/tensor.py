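"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tensor engine: float32 arrays, dynamic graph built by
operator overloading, topological-order backward pass.  Only the operations
the detector needs are implemented; every op with a custom backward is
covered by a numerical gradient check in the test suite.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable

import numpy as np

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def grad_enabled() -> bool:
    return _grad_enabled


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._prev: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.size != 1:
                raise RuntimeError("backward() without grad needs a scalar")
            grad = np.ones_like(self.data)
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
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()

    # ---------------------------------------------------------------- helpers
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data: np.ndarray, parents: Iterable["Tensor"]) -> "Tensor":
        parents = tuple(parents)
        req = _grad_enabled and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._prev = tuple(p for p in parents if p.requires_grad)
        return out

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._lift(other)
        out = self._make(self.data + other.data, (self, other))
        if out.requires_grad:
            def _backward():
                if self.requires_grad:
                    self._accumulate(_unbroadcast(out.grad, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(out.grad, other.shape))
            out._backward = _backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = self._make(-self.data, (self,))
        if out.requires_grad:
            out._backward = lambda: self._accumulate(-out.grad)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = self._make(self.data * other.data, (self, other))
        if out.requires_grad:
            def _backward():
                if self.requires_grad:
                    self._accumulate(_unbroadcast(out.grad * other.data, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(out.grad * self.data, other.shape))
            out._backward = _backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = self._make(self.data / other.data, (self, other))
        if out.requires_grad:
            def _backward():
                if self.requires_grad:
                    self._accumulate(_unbroadcast(out.grad / other.data, self.shape))
                if other.requires_grad:
                    other._accumulate(
                        _unbroadcast(-out.grad * self.data / (other.data ** 2), other.shape)
                    )
            out._backward = _backward
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        out = self._make(self.data ** exponent, (self,))
        if out.requires_grad:
            def _backward():
                self._accumulate(out.grad * exponent * self.data ** (exponent - 1))
            out._backward = _backward
        return out

    # -------------------------------------------------------------- functions
    def exp(self):
        out = self._make(np.exp(self.data), (self,))
        if out.requires_grad:
            out._backward = lambda: self._accumulate(out.grad * out.data)
        return out

    def log(self):
        out = self._make(np.log(self.data), (self,))
        if out.requires_grad:
            out._backward = lambda: self._accumulate(out.grad / self.data)
        return out

    def sqrt(self):
        return self ** 0.5

    def arctan(self):
        out = self._make(np.arctan(self.data), (self,))
        if out.requires_grad:
            out._backward = lambda: self._accumulate(out.grad / (1.0 + self.data ** 2))
        return out

    def sigmoid(self):
        with np.errstate(over="ignore"):
            s = 1.0 / (1.0 + np.exp(-self.data))
        out = self._make(s, (self,))
        if out.requires_grad:
            out._backward = lambda: self._accumulate(out.grad * out.data * (1.0 - out.data))
        return out

    def silu(self):
        with np.errstate(over="ignore"):
            s = 1.0 / (1.0 + np.exp(-self.data))
        out = self._make(self.data * s, (self,))
        if out.requires_grad:
            def _backward():
                self._accumulate(out.grad * (s + self.data * s * (1.0 - s)))
            out._backward = _backward
        return out

    def clamp_min(self, lo: float):
        out = self._make(np.maximum(self.data, lo), (self,))
        if out.requires_grad:
            mask = (self.data >= lo).astype(np.float32)
            out._backward = lambda: self._accumulate(out.grad * mask)
        return out

    def maximum(self, other):
        other = self._lift(other)
        out = self._make(np.maximum(self.data, other.data), (self, other))
        if out.requires_grad:
            mask = (self.data >= other.data).astype(np.float32)
            def _backward():
                if self.requires_grad:
                    self._accumulate(_unbroadcast(out.grad * mask, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(out.grad * (1.0 - mask), other.shape))
            out._backward = _backward
        return out

    def minimum(self, other):
        other = self._lift(other)
        out = self._make(np.minimum(self.data, other.data), (self, other))
        if out.requires_grad:
            mask = (self.data <= other.data).astype(np.float32)
            def _backward():
                if self.requires_grad:
                    self._accumulate(_unbroadcast(out.grad * mask, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(out.grad * (1.0 - mask), other.shape))
            out._backward = _backward
        return out

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out.requires_grad:
            def _backward():
                g = out.grad
                if axis is not None and not keepdims:
                    axes = axis if isinstance(axis, tuple) else (axis,)
                    g = np.expand_dims(g, tuple(a % self.ndim for a in axes))
                self._accumulate(np.broadcast_to(g, self.shape).astype(np.float32))
            out._backward = _backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.size if axis is None else (
            np.prod([self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # ----------------------------------------------------------------- shape
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = self._make(self.data.reshape(shape), (self,))
        if out.requires_grad:
            out._backward = lambda: self._accumulate(out.grad.reshape(self.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out = self._make(np.ascontiguousarray(self.data.transpose(axes)), (self,))
        if out.requires_grad:
            inv = tuple(np.argsort(axes))
            out._backward = lambda: self._accumulate(out.grad.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = self._make(self.data[idx], (self,))
        if out.requires_grad:
            def _backward():
                g = np.zeros(self.shape, dtype=np.float32)
                np.add.at(g, idx, out.grad)
                self._accumulate(g)
            out._backward = _backward
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = self._make(self.data @ other.data, (self, other))
        if out.requires_grad:
            def _backward():
                if self.requires_grad:
                    self._accumulate(out.grad @ other.data.T)
                if other.requires_grad:
                    other._accumulate(self.data.T @ out.grad)
            out._backward = _backward
        return out


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor._make(data, tensors)
    if out.requires_grad:
        sizes = [t.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)
        def _backward():
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * out.ndim
                    sl[axis] = slice(a, b)
                    t._accumulate(out.grad[tuple(sl)])
        out._backward = _backward
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    data = np.stack([t.data for t in tensors], axis=axis)
    out = Tensor._make(data, tensors)
    if out.requires_grad:
        def _backward():
            for i, t in enumerate(tensors):
                if t.requires_grad:
                    t._accumulate(np.take(out.grad, i, axis=axis))
        out._backward = _backward
    return out


def where_const(mask: np.ndarray, a: Tensor, b: Tensor) -> Tensor:
    """Elementwise select with a constant (non-differentiable) mask."""
    m = np.asarray(mask, dtype=bool)
    out = Tensor._make(np.where(m, a.data, b.data), (a, b))
    if out.requires_grad:
        mf = m.astype(np.float32)
        def _backward():
            if a.requires_grad:
                a._accumulate(_unbroadcast(out.grad * mf, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(out.grad * (1.0 - mf), b.shape))
        out._backward = _backward
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray,
                    weight: np.ndarray | None = None) -> Tensor:
    """Numerically stable mean binary cross-entropy on logits.

    `targets` (and the optional per-element `weight`) are constants.
    """
    t = np.asarray(targets, dtype=np.float32)
    x = logits.data
    loss = np.maximum(x, 0) - x * t + np.log1p(np.exp(-np.abs(x)))
    if weight is not None:
        w = np.asarray(weight, dtype=np.float32)
        loss = loss * w
    out = Tensor._make(np.asarray(loss.mean()), (logits,))
    if out.requires_grad:
        def _backward():
            with np.errstate(over="ignore"):
                g = (1.0 / (1.0 + np.exp(-x))) - t
            if weight is not None:
                g = g * weight
            logits._accumulate(out.grad * g / x.size)
        out._backward = _backward
    return out
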