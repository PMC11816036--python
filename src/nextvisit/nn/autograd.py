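"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` runs the chain rule over the recorded graph in
reverse topological order.  Only the operations needed by the encoder, the
masked-language-model head and the recurrent baselines are provided; every
operation supports NumPy broadcasting, with gradients summed back over the
broadcast axes.

Gradient correctness is validated against central finite differences in the
test suite.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "no_grad", "cat", "stack", "embedding"]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph recording (evaluation / inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes of size 1 in the original shape
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


def _as_tensor(x) -> "Tensor":
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=np.float64), requires_grad=False)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- construction of derived nodes ------------------------------------
    @staticmethod
    def _make(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        # first contribution is stored by reference (closures always hand over
        # fresh arrays or views that are never mutated afterwards); later
        # contributions allocate a new sum, so shared references stay intact
        if self.grad is None:
            self.grad = grad
        else:
            self.grad = self.grad + grad

    # -- shape/introspection ----------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def numpy(self) -> np.ndarray:
        return self.data

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = _as_tensor(other)

        def backward(grad, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(grad, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(grad, b.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(grad, a=self):
            if a.requires_grad:
                a._accum(-grad)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-_as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return _as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = _as_tensor(other)

        def backward(grad, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(grad * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(grad * a.data, b.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        return self * (_as_tensor(other) ** -1.0)

    def __rtruediv__(self, other) -> "Tensor":
        return _as_tensor(other) * (self ** -1.0)

    def __pow__(self, exponent: float) -> "Tensor":
        e = float(exponent)

        def backward(grad, a=self):
            if a.requires_grad:
                a._accum(grad * e * np.power(a.data, e - 1.0))

        return Tensor._make(np.power(self.data, e), (self,), backward)

    def __matmul__(self, other) -> "Tensor":
        other = _as_tensor(other)

        def backward(grad, a=self, b=other):
            if a.requires_grad:
                ga = np.matmul(grad, np.swapaxes(b.data, -1, -2))
                a._accum(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), grad)
                b._accum(_unbroadcast(gb, b.shape))

        return Tensor._make(np.matmul(self.data, other.data), (self, other), backward)

    # -- elementwise nonlinearities -----------------------------------------
    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(grad, a=self, o=out_data):
            if a.requires_grad:
                a._accum(grad * o)

        return Tensor._make(out_data, (self,), backward)

    def log(self) -> "Tensor":
        def backward(grad, a=self):
            if a.requires_grad:
                a._accum(grad / a.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def backward(grad, a=self, o=out_data):
            if a.requires_grad:
                a._accum(grad * (1.0 - o * o))

        return Tensor._make(out_data, (self,), backward)

    def sigmoid(self) -> "Tensor":
        # numerically stable logistic
        out_data = np.empty_like(self.data)
        pos = self.data >= 0
        out_data[pos] = 1.0 / (1.0 + np.exp(-self.data[pos]))
        ez = np.exp(self.data[~pos])
        out_data[~pos] = ez / (1.0 + ez)

        def backward(grad, a=self, o=out_data):
            if a.requires_grad:
                a._accum(grad * o * (1.0 - o))

        return Tensor._make(out_data, (self,), backward)

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(grad, a=self, m=mask):
            if a.requires_grad:
                a._accum(grad * m)

        return Tensor._make(self.data * mask, (self,), backward)

    def gelu(self) -> "Tensor":
        """Gaussian error linear unit (tanh approximation)."""
        c = np.sqrt(2.0 / np.pi)
        x = self.data
        inner = c * (x + 0.044715 * x**3)
        t = np.tanh(inner)
        out_data = 0.5 * x * (1.0 + t)

        def backward(grad, a=self, t=t, x=x, c=c):
            if a.requires_grad:
                dinner = c * (1.0 + 3 * 0.044715 * x**2)
                d = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * dinner
                a._accum(grad * d)

        return Tensor._make(out_data, (self,), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(grad, a=self, axis=axis, keepdims=keepdims):
            if not a.requires_grad:
                return
            g = np.asarray(grad)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def softmax(self, axis: int = -1) -> "Tensor":
        # fused op: shift by the max for stability, single backward closure
        e = np.exp(self.data - self.data.max(axis=axis, keepdims=True))
        s = e / e.sum(axis=axis, keepdims=True)

        def backward(grad, a=self, s=s, axis=axis):
            if a.requires_grad:
                a._accum(s * (grad - (grad * s).sum(axis=axis, keepdims=True)))

        return Tensor._make(s, (self,), backward)

    # -- shape manipulation ---------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape

        def backward(grad, a=self, orig=orig):
            if a.requires_grad:
                a._accum(grad.reshape(orig))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(grad, a=self, inv=inv):
            if a.requires_grad:
                a._accum(grad.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx) -> "Tensor":
        def backward(grad, a=self, idx=idx):
            if a.requires_grad:
                g = np.zeros_like(a.data)
                np.add.at(g, idx, grad)
                a._accum(g)

        return Tensor._make(self.data[idx], (self,), backward)

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("called backward() on a tensor without gradient")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("backward() without a seed gradient requires a scalar")
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
            for p in node._prev:
                if id(p) not in visited:
                    stack.append((p, False))

        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


class Parameter(Tensor):
    """A trainable tensor (``requires_grad`` always on)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def cat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(grad, ts=tensors, offsets=offsets, axis=axis):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * grad.ndim
                sl[axis] = slice(lo, hi)
                t._accum(grad[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]

    def backward(grad, ts=tensors, axis=axis):
        for i, t in enumerate(ts):
            if t.requires_grad:
                t._accum(np.take(grad, i, axis=axis))

    return Tensor._make(np.stack([t.data for t in tensors], axis=axis), tensors, backward)


def embedding(weight: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup ``weight[ids]`` with scatter-add gradient into the table."""
    ids = np.asarray(ids)

    def backward(grad, w=weight, ids=ids):
        if w.requires_grad:
            g = np.zeros_like(w.data)
            np.add.at(g, ids.reshape(-1), grad.reshape(-1, w.data.shape[1]))
            w._accum(g)

    return Tensor._make(weight.data[ids], (weight,), backward)
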