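"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains its networks through this engine: a :class:`Tensor` wraps a
float64 ``numpy`` array and records the operations applied to it; calling
:meth:`Tensor.backward` on a scalar result accumulates gradients into every
upstream tensor created with ``requires_grad=True``.

Only the operations the count-autoencoder needs are implemented (dense algebra,
the stable log-sigmoid/softplus pair, log-softmax, log-gamma, element masking,
reductions with broadcasting-aware gradients). Gradients are verified against
central finite differences in the test suite.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from scipy import special as _sp

__all__ = ["Tensor", "Parameter", "concat", "logaddexp"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _from_op(cls, data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return Tensor._from_op(out_data, (self, other), backward)

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
        out_data = self.data * other.data

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return self * other ** -1.0
        return self * (1.0 / other)

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data ** exponent

        def backward(g, a=self, p=float(exponent)):
            if a.requires_grad:
                a._accum(g * p * a.data ** (p - 1.0))

        return Tensor._from_op(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(g @ b.data.T)
            if b.requires_grad:
                b._accum(a.data.T @ g)

        return Tensor._from_op(out_data, (self, other), backward)

    # -- elementwise functions ------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g, a=self, y=out_data):
            if a.requires_grad:
                a._accum(g * y)

        return Tensor._from_op(out_data, (self,), backward)

    def log(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g / a.data)

        return Tensor._from_op(np.log(self.data), (self,), backward)

    def abs(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g * np.sign(a.data))

        return Tensor._from_op(np.abs(self.data), (self,), backward)

    def sigmoid(self):
        out_data = _sp.expit(self.data)

        def backward(g, a=self, y=out_data):
            if a.requires_grad:
                a._accum(g * y * (1.0 - y))

        return Tensor._from_op(out_data, (self,), backward)

    def softplus(self):
        """log(1 + e^x) in its piecewise-stable form (no truncation offsets)."""
        out_data = np.logaddexp(0.0, self.data)

        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g * _sp.expit(a.data))

        return Tensor._from_op(out_data, (self,), backward)

    def log_sigmoid(self):
        """log sig(x) = -softplus(-x); the numerically stable mixture workhorse."""
        return -((-self).softplus())

    def gelu(self):
        x = self.data
        phi = 0.5 * (1.0 + _sp.erf(x / np.sqrt(2.0)))
        out_data = x * phi

        def backward(g, a=self, phi=phi):
            if a.requires_grad:
                pdf = np.exp(-0.5 * a.data ** 2) / np.sqrt(2.0 * np.pi)
                a._accum(g * (phi + a.data * pdf))

        return Tensor._from_op(out_data, (self,), backward)

    def lgamma(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g * _sp.digamma(a.data))

        return Tensor._from_op(_sp.gammaln(self.data), (self,), backward)

    def log_softmax(self, axis: int = -1):
        x = self.data
        lse = _sp.logsumexp(x, axis=axis, keepdims=True)
        out_data = x - lse

        def backward(g, a=self, y=out_data, axis=axis):
            if a.requires_grad:
                a._accum(g - np.exp(y) * g.sum(axis=axis, keepdims=True))

        return Tensor._from_op(out_data, (self,), backward)

    # -- reductions / shaping -------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g, a=self, axis=axis, keepdims=keepdims):
            if not a.requires_grad:
                return
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.shape).copy())

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            n = int(np.prod([self.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)

        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g.reshape(a.shape))

        return Tensor._from_op(out_data, (self,), backward)

    # -- autograd driver ------------------------------------------------------

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
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
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None


class Parameter(Tensor):
    """A trainable tensor (``requires_grad`` always on)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient splitting."""
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g, parts=tuple(tensors), offsets=offsets, axis=axis):
        for i, p in enumerate(parts):
            if p.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(offsets[i], offsets[i + 1])
                p._accum(g[tuple(sl)])

    return Tensor._from_op(out_data, tensors, backward)


def logaddexp(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise log(e^a + e^b), stable, with softmax-weighted gradients."""
    a, b = Tensor._lift(a), Tensor._lift(b)
    out_data = np.logaddexp(a.data, b.data)

    def backward(g, a=a, b=b, y=out_data):
        if a.requires_grad:
            a._accum(_unbroadcast(g * np.exp(a.data - y), a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * np.exp(b.data - y), b.shape))

    return Tensor._from_op(out_data, (a, b), backward)
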