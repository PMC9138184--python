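"""Reverse-mode automatic differentiation on NumPy arrays.

A small tape-based engine: :class:`Tensor` wraps an ``ndarray`` and records the
operations applied to it; :meth:`Tensor.backward` walks the tape in reverse
topological order and accumulates gradients into every tensor created with
``requires_grad=True``.  Only the operations the imputation and causality
models need are implemented (elementwise arithmetic, matmul with broadcasting,
the usual activations, reductions, concatenation, slicing, reshaping).

All arrays are float64.  Broadcasting follows NumPy semantics; gradients of
broadcast operands are summed back to the operand's shape.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "Adam", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over the axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _op(data: np.ndarray, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._parents for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad = self.grad + grad

    # -- properties -----------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor._op(self.data + other.data, (self, other), None)

        def backward(g):
            self._accum(g)
            other._accum(g)

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor._op(-self.data, (self,), None)
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor._op(self.data * other.data, (self, other), None)

        def backward(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor._op(self.data / other.data, (self, other), None)

        def backward(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / other.data**2)

        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)
        out = Tensor._op(self.data**e, (self,), None)
        out._backward = lambda g: self._accum(g * e * self.data ** (e - 1.0))
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor._op(np.matmul(self.data, other.data), (self, other), None)

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 1:
                self._accum(g * b)
                other._accum(g * a)
                return
            ga = a[None, :] if a.ndim == 1 else a
            gb = b[:, None] if b.ndim == 1 else b
            gg = np.asarray(g)
            if a.ndim == 1:
                gg = np.expand_dims(gg, -2)
            if b.ndim == 1:
                gg = np.expand_dims(gg, -1)
            da = np.matmul(gg, np.swapaxes(gb, -1, -2))
            db = np.matmul(np.swapaxes(ga, -1, -2), gg)
            if a.ndim == 1:
                da = np.squeeze(da, -2)
            if b.ndim == 1:
                db = np.squeeze(db, -1)
            self._accum(_unbroadcast(da, a.shape))
            other._accum(_unbroadcast(db, b.shape))

        out._backward = backward
        return out

    # -- elementwise functions ------------------------------------------------

    def exp(self):
        val = np.exp(self.data)
        out = Tensor._op(val, (self,), None)
        out._backward = lambda g: self._accum(g * val)
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = Tensor._op(val, (self,), None)
        out._backward = lambda g: self._accum(g * (1.0 - val**2))
        return out

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor._op(val, (self,), None)
        out._backward = lambda g: self._accum(g * val * (1.0 - val))
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor._op(self.data * mask, (self,), None)
        out._backward = lambda g: self._accum(g * mask)
        return out

    def abs(self):
        sign = np.sign(self.data)
        out = Tensor._op(np.abs(self.data), (self,), None)
        out._backward = lambda g: self._accum(g * sign)
        return out

    def sqrt(self):
        return self**0.5

    # -- reductions / shape ---------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor._op(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)

        def backward(g):
            g = np.asarray(g, dtype=np.float64)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out = Tensor._op(self.data.reshape(shape), (self,), None)
        out._backward = lambda g: self._accum(np.asarray(g).reshape(orig))
        return out

    def swapaxes(self, a: int, b: int):
        out = Tensor._op(np.swapaxes(self.data, a, b), (self,), None)
        out._backward = lambda g: self._accum(np.swapaxes(np.asarray(g), a, b))
        return out

    @property
    def T(self):
        return self.swapaxes(-1, -2)

    def __getitem__(self, idx):
        out = Tensor._op(self.data[idx], (self,), None)

        def backward(g):
            buf = np.zeros_like(self.data)
            np.add.at(buf, idx, g)
            self._accum(buf)

        out._backward = backward
        return out

    # -- autodiff -------------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64).reshape(self.data.shape)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor._op(np.concatenate([t.data for t in tensors], axis=axis), tensors, None)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(np.asarray(g), splits, axis=axis)):
            t._accum(piece)

    out._backward = backward
    return out


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
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
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
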