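"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The model in this package is small (two GCN layers, a two-layer projection
head, two decoder layers) and dense, so a tape-based engine over plain
``numpy.ndarray`` is sufficient: every operation records its parents and a
closure that accumulates gradients, and :meth:`Tensor.backward` walks the
tape in reverse topological order.

Only the operations the model needs are implemented.  Gradients are checked
against central finite differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

__all__ = ["Tensor", "as_tensor", "relu", "sigmoid", "masked_max", "matmul"]


def _sum_to(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` (a broadcast result) back to ``shape``."""
    if grad.shape == shape:
        return grad
    # collapse extra leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were broadcast from size 1
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array plus an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # -- tape -------------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep graphs would blow the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _sum_to(np.asarray(grad, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- helpers ----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out = _make(self.data + other.data, (self, other))
        if out.requires_grad:
            def bwd(g):
                if self.requires_grad:
                    self._accumulate(g)
                if other.requires_grad:
                    other._accumulate(g)
            out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _make(-self.data, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = _make(self.data * other.data, (self, other))
        if out.requires_grad:
            def bwd(g):
                if self.requires_grad:
                    self._accumulate(g * other.data)
                if other.requires_grad:
                    other._accumulate(g * self.data)
            out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = _make(self.data / other.data, (self, other))
        if out.requires_grad:
            def bwd(g):
                if self.requires_grad:
                    self._accumulate(g / other.data)
                if other.requires_grad:
                    other._accumulate(-g * self.data / other.data**2)
            out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __matmul__(self, other):
        return matmul(self, other)

    # -- reductions / elementwise -----------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out.requires_grad:
            def bwd(g):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.data.shape))
            out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def transpose_last(self):
        """Swap the last two axes (batched matrix transpose)."""
        out = _make(np.swapaxes(self.data, -1, -2), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(np.swapaxes(g, -1, -2))
        return out

    def power(self, exponent: float):
        out = _make(self.data**exponent, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(
                g * exponent * self.data ** (exponent - 1.0)
            )
        return out

    def sqrt(self):
        return self.power(0.5)

    def exp(self):
        val = np.exp(self.data)
        out = _make(val, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * val)
        return out

    def log(self):
        out = _make(np.log(self.data), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g / self.data)
        return out


def _make(data: np.ndarray, parents: tuple[Tensor, ...]) -> Tensor:
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, parents=tuple(p for p in parents if p.requires_grad))


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = _make(np.matmul(a.data, b.data), (a, b))
    if out.requires_grad:
        def bwd(g):
            if a.requires_grad:
                a._accumulate(np.matmul(g, np.swapaxes(b.data, -1, -2)))
            if b.requires_grad:
                b._accumulate(np.matmul(np.swapaxes(a.data, -1, -2), g))
        out._backward = bwd
    return out


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    pos = x.data > 0
    out = _make(np.where(pos, x.data, 0.0), (x,))
    if out.requires_grad:
        out._backward = lambda g: x._accumulate(g * pos)
    return out


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    val = 1.0 / (1.0 + np.exp(-x.data))
    out = _make(val, (x,))
    if out.requires_grad:
        out._backward = lambda g: x._accumulate(g * val * (1.0 - val))
    return out


def masked_max(x: Tensor, mask: np.ndarray) -> Tensor:
    """Coordinate-wise max over axis -2, restricted to rows where mask == 1.

    ``x`` has shape (..., M, h); ``mask`` shape (..., M).  Every batch item
    must have at least one valid row.  The gradient flows to the (first)
    argmax row per coordinate, matching subgradient convention.
    """
    x = as_tensor(x)
    m = np.asarray(mask, dtype=bool)
    if not m.any(axis=-1).all():
        raise ValueError("masked_max: every item needs at least one valid row")
    masked = np.where(m[..., None], x.data, -np.inf)
    idx = np.argmax(masked, axis=-2)  # (..., h)
    val = np.take_along_axis(masked, idx[..., None, :], axis=-2)[..., 0, :]
    out = _make(val, (x,))
    if out.requires_grad:
        def bwd(g):
            full = np.zeros_like(x.data)
            np.put_along_axis(full, idx[..., None, :], g[..., None, :], axis=-2)
            x._accumulate(full)
        out._backward = bwd
    return out
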