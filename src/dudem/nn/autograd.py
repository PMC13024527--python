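"""Reverse-mode automatic differentiation on NumPy arrays.

A small tape-based engine in the micrograd style, but tensor-valued: each
:class:`Tensor` wraps an ``ndarray`` and records a closure that propagates the
upstream gradient to its parents.  Dedicated fused ops are provided for the
expensive layers (``conv2d``, ``maxpool2d``, ``batch_norm``) so the per-step
Python overhead stays small enough for CPU training; everything else is
composed from elementwise/reduction primitives.

Dtype is preserved: layer parameters default to float32, while pure functions
(squash, routing, losses) run in whatever precision the caller supplies, which
lets oracle tests run in float64.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were broadcast from 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        data = np.asarray(data)
        if not np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float32)
        self.data = data
        self.grad = None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self._backward = None
        self._prev = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _from_op(data, parents, backward):
        req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._prev = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, grad={self.requires_grad})"

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def _accum(self, g):
        g = g.astype(self.data.dtype, copy=False)
        if self.grad is None:
            self.grad = g.copy() if not g.flags.owndata else g
        else:
            self.grad = self.grad + g

    # -- elementwise arithmetic ----------------------------------------------
    @staticmethod
    def _coerce(x):
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def __add__(self, other):
        a = self
        if isinstance(other, (int, float)):
            c = other

            def backward_s(g):
                if a.requires_grad:
                    a._accum(g)

            return Tensor._from_op(a.data + c, (a,), backward_s)
        other = Tensor._coerce(other)
        b = other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return Tensor._from_op(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._from_op(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        a = self
        if isinstance(other, (int, float)):
            c = other

            def backward_s(g):
                if a.requires_grad:
                    a._accum(g * c)

            return Tensor._from_op(a.data * c, (a,), backward_s)
        other = Tensor._coerce(other)
        b = other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._from_op(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor._coerce(other) * self ** -1.0

    def __pow__(self, p: float):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(g * p * a.data ** (p - 1))

        return Tensor._from_op(a.data ** p, (a,), backward)

    # -- matmul ---------------------------------------------------------------
    def __matmul__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other
        if a.ndim < 2 or b.ndim < 2:
            raise ValueError("matmul requires operands with ndim >= 2; reshape first")
        out_data = np.matmul(a.data, b.data)

        def backward(g):
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accum(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accum(_unbroadcast(gb, b.shape))

        return Tensor._from_op(out_data, (a, b), backward)

    # -- nonlinearities -------------------------------------------------------
    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            if a.requires_grad:
                a._accum(g * mask)

        return Tensor._from_op(a.data * mask, (a,), backward)

    def sigmoid(self):
        a = self
        x = a.data
        s = np.empty_like(x)
        pos = x >= 0
        s[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        s[~pos] = ex / (1.0 + ex)

        def backward(g):
            if a.requires_grad:
                a._accum(g * s * (1.0 - s))

        return Tensor._from_op(s, (a,), backward)

    def exp(self):
        a = self
        e = np.exp(a.data)

        def backward(g):
            if a.requires_grad:
                a._accum(g * e)

        return Tensor._from_op(e, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(g / a.data)

        return Tensor._from_op(np.log(a.data), (a,), backward)

    def sqrt(self):
        return self ** 0.5

    def clip_min(self, lo: float):
        """max(x, lo) with gradient passed where x > lo (ties included)."""
        a = self
        mask = a.data >= lo

        def backward(g):
            if a.requires_grad:
                a._accum(g * mask)

        return Tensor._from_op(np.maximum(a.data, lo), (a,), backward)

    def abs(self):
        a = self
        sign = np.sign(a.data)

        def backward(g):
            if a.requires_grad:
                a._accum(g * sign)

        return Tensor._from_op(np.abs(a.data), (a,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.shape))

        return Tensor._from_op(out_data, (a,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        a = self
        out_data = a.data.max(axis=axis, keepdims=True)
        mask = (a.data == out_data)
        # split gradient evenly across ties for safety
        counts = mask.sum(axis=axis, keepdims=True)

        def backward(g):
            if a.requires_grad:
                gk = g if keepdims else np.expand_dims(g, axis)
                a._accum(mask * (gk / counts))

        return Tensor._from_op(out_data if keepdims else out_data.squeeze(axis),
                               (a,), backward)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        orig = a.shape

        def backward(g):
            if a.requires_grad:
                a._accum(g.reshape(orig))

        return Tensor._from_op(a.data.reshape(shape), (a,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)

        def backward(g):
            if a.requires_grad:
                a._accum(g.transpose(inv))

        return Tensor._from_op(a.data.transpose(axes), (a,), backward)

    def expand(self, shape):
        """Broadcast to `shape`; gradient sums back."""
        a = self
        orig = a.shape

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, orig))

        return Tensor._from_op(np.broadcast_to(a.data, shape).copy(), (a,), backward)

    def __getitem__(self, idx):
        a = self

        def backward(g):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, idx, g)
                a._accum(full)

        return Tensor._from_op(a.data[idx], (a,), backward)

    # -- stable softmax / norms ----------------------------------------------
    def softmax(self, axis: int = -1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def norm(self, axis: int = -1, keepdims: bool = False, eps: float = 0.0):
        sq = (self * self).sum(axis=axis, keepdims=keepdims)
        if eps:
            sq = sq + eps
        return sq.sqrt()


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)

    def backward(g):
        start = 0
        for t, s in zip(tensors, sizes):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(start, start + s)
                t._accum(g[tuple(sl)])
            start += s

    return Tensor._from_op(out_data, tuple(tensors), backward)
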