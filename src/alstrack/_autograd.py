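"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations needed by the shallow transformer encoder in
:mod:`alstrack.pseudolabels`: broadcasting arithmetic, matrix products,
row/column selection, concatenation, softmax, ReLU and axis reductions.
Gradients are accumulated on a topologically sorted tape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "softmax", "relu"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction -----------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._from_op(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._from_op(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._from_op(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._lift(other) ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, p: float):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")

        def backward(g, a=self, p=p):
            if a.requires_grad:
                a._accum(g * p * a.data ** (p - 1.0))

        return Tensor._from_op(self.data ** p, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(g @ b.data.T)
            if b.requires_grad:
                b._accum(a.data.T @ g)

        return Tensor._from_op(self.data @ other.data, (self, other), backward)

    # -- shape / selection ---------------------------------------------------
    @property
    def T(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g.T)

        return Tensor._from_op(self.data.T, (self,), backward)

    def __getitem__(self, key):
        def backward(g, a=self, key=key):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, key, g)
                a._accum(full)

        return Tensor._from_op(self.data[key], (self,), backward)

    # -- reductions / nonlinearities ----------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g, a=self, axis=axis, keepdims=keepdims):
            if not a.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.data.shape).copy())

        return Tensor._from_op(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g, a=self, d=out_data):
            if a.requires_grad:
                a._accum(g * d)

        return Tensor._from_op(out_data, (self,), backward)

    # -- backprop ------------------------------------------------------------
    def _accum(self, g: np.ndarray) -> None:
        self.grad = g if self.grad is None else self.grad + g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            order.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(order):
            if t._backward is not None:
                t._backward(t.grad)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g, tensors=tensors, offsets=offsets, axis=axis):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    return Tensor._from_op(np.concatenate(datas, axis=axis), tuple(tensors), backward)


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    # max-shift is a constant w.r.t. differentiation (its gradient cancels)
    shifted = t - np.max(t.data, axis=axis, keepdims=True)
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def relu(t: Tensor) -> Tensor:
    mask = t.data > 0

    def backward(g, a=t, mask=mask):
        if a.requires_grad:
            a._accum(g * mask)

    return Tensor._from_op(t.data * mask, (t,), backward)
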