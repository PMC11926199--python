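"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine sufficient for the residual architectures in
:mod:`rp2gauge.pipeline`: broadcasting arithmetic, two-operand einsum,
gathers, ReLU, reductions, and custom linear ops for 3D im2col, hexagonal
stencil extraction, atlas padding and vertex scatter.  Gradients are
accumulated in float64 or float32 following the data.

Not a general framework: no in-place mutation of tracked tensors, no higher
order derivatives.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "tensor", "relu", "einsum2", "take_last", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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
    """Array node of the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 _backward=None, _parents=()):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in _parents)
        self._backward = _backward
        self._parents = _parents

    @property
    def shape(self):
        return self.data.shape

    # -- graph traversal -------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
            if t._parents:
                # free intermediate gradients to bound peak memory; only
                # leaves (parameters, inputs) keep their accumulated grad
                t.grad = None

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, copy=True)
        else:
            self.grad = self.grad + grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        if isinstance(other, (int, float)):
            def back_s(g):
                if self.requires_grad:
                    self._accumulate(g)
            return Tensor(self.data + other, _backward=back_s,
                          _parents=(self,))
        other = tensor(other)

        def back(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor(self.data + other.data, _backward=back,
                      _parents=(self, other))

    __radd__ = __add__

    def __neg__(self):
        def back(g):
            if self.requires_grad:
                self._accumulate(-g)
        return Tensor(-self.data, _backward=back, _parents=(self,))

    def __sub__(self, other):
        return self + (-tensor(other))

    def __rsub__(self, other):
        return tensor(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            def back_s(g):
                if self.requires_grad:
                    self._accumulate(g * other)
            return Tensor(self.data * other, _backward=back_s,
                          _parents=(self,))
        other = tensor(other)

        def back(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor(self.data * other.data, _backward=back,
                      _parents=(self, other))

    __rmul__ = __mul__

    def pow_const(self, p: float):
        def back(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))
        return Tensor(self.data ** p, _backward=back, _parents=(self,))

    def sqrt(self):
        return self.pow_const(0.5)

    def __truediv__(self, other):
        other = tensor(other)
        return self * other.pow_const(-1.0)

    # -- shape -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def back(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old))
        return Tensor(self.data.reshape(shape), _backward=back,
                      _parents=(self,))

    def transpose(self, axes):
        inv = np.argsort(axes)

        def back(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))
        return Tensor(self.data.transpose(axes), _backward=back,
                      _parents=(self,))

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def back(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            gg = g if keepdims else np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(gg, self.shape).copy())
        return Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                      _backward=back, _parents=(self,))

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def tensor(x, requires_grad: bool = False) -> Tensor:
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x)
    if not np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(np.float64)
    return Tensor(arr, requires_grad=requires_grad)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def back(g):
        if x.requires_grad:
            x._accumulate(g * mask)
    return Tensor(x.data * mask, _backward=back, _parents=(x,))


def einsum2(subscripts: str, a: Tensor, b: Tensor) -> Tensor:
    """Two-operand einsum with reverse-mode gradients.

    Subscripts must be explicit (contain ``->``) without ellipsis or repeated
    indices within one operand.
    """
    a, b = tensor(a), tensor(b)
    lhs, out_sub = subscripts.split("->")
    a_sub, b_sub = lhs.split(",")
    y = np.einsum(subscripts, a.data, b.data, optimize=True)

    def back(g):
        if a.requires_grad:
            ga = np.einsum(f"{out_sub},{b_sub}->{a_sub}", g, b.data,
                           optimize=True)
            a._accumulate(ga)
        if b.requires_grad:
            gb = np.einsum(f"{out_sub},{a_sub}->{b_sub}", g, a.data,
                           optimize=True)
            b._accumulate(gb)

    return Tensor(y, _backward=back, _parents=(a, b))


def take_last(x: Tensor, idx: np.ndarray) -> Tensor:
    """Gather along the last axis: ``y[..., j] = x[..., idx[j]]`` (idx may be
    multi-dimensional, appended to the leading axes)."""
    idx = np.asarray(idx, dtype=np.intp)

    def back(g):
        if not x.requires_grad:
            return
        gx = np.zeros(x.shape, dtype=g.dtype)
        flat_g = g.reshape(g.shape[:x.data.ndim - 1] + (-1,))
        np.add.at(gx, (..., idx.ravel()), flat_g)
        x._accumulate(gx)

    return Tensor(x.data[..., idx], _backward=back, _parents=(x,))


def concat(parts: list[Tensor], axis: int = 0) -> Tensor:
    parts = [tensor(p) for p in parts]
    sizes = [p.data.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            if p.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                p._accumulate(g[tuple(sl)])

    return Tensor(np.concatenate([p.data for p in parts], axis=axis),
                  _backward=back, _parents=tuple(parts))
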