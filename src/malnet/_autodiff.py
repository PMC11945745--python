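"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine sufficient for the network in this package:
broadcast-aware elementwise arithmetic, (batched) matrix products, the
activations used by LSTM gates and attention, reductions, and
stack/concat/slice for sequence handling.  Gradients are accumulated on
leaf :class:`Tensor` objects by :meth:`Tensor.backward`.

Every operation's backward rule is exercised against central finite
differences in the test-suite; the engine is deliberately tiny rather
than general (no in-place ops, no higher-order gradients).
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = ["Tensor", "stack", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an attached gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")
    __array_priority__ = 100  # keep numpy from hijacking binary ops

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (defaults to d(self)/d(self)=1)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        while stack_:
            node = stack_[-1]
            if id(node) in seen:
                stack_.pop()
                continue
            unvisited = [p for p in node._prev if id(p) not in seen]
            if unvisited:
                stack_.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
                stack_.pop()
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise NotImplementedError("division by a Tensor is not supported")
        return self * (1.0 / other)

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                if other.data.ndim == 1:
                    ga = np.expand_dims(g, -1) * other.data
                else:
                    ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                if self.data.ndim == 1:
                    gb = np.expand_dims(self.data, -1) * np.expand_dims(g, -2)
                else:
                    gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))

        return self._make(self.data @ other.data, (self, other), backward)

    # -- shape ops --------------------------------------------------------

    def transpose_last(self) -> "Tensor":
        """Swap the last two axes (for attention scores K -> K^T)."""

        def backward(g):
            self._accumulate(np.swapaxes(g, -1, -2))

        return self._make(np.swapaxes(self.data, -1, -2), (self,), backward)

    def __getitem__(self, idx):
        basic = isinstance(idx, (int, slice)) or (
            isinstance(idx, tuple)
            and all(isinstance(i, (int, slice)) for i in idx))

        def backward(g):
            full = np.zeros_like(self.data)
            if basic:           # slices never alias: direct add is exact
                full[idx] += g
            else:
                np.add.at(full, idx, g)
            self._accumulate(full)

        return self._make(self.data[idx], (self,), backward)

    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape

        def backward(g):
            self._accumulate(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), backward)

    # -- activations ------------------------------------------------------

    def sigmoid(self) -> "Tensor":
        out_data = _sigmoid(self.data)

        def backward(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def backward(g):
            self._accumulate(g * (1.0 - out_data * out_data))

        return self._make(out_data, (self,), backward)

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(g):
            self._accumulate(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def softplus(self) -> "Tensor":
        # log(1 + e^x), stable for large |x|
        out_data = np.logaddexp(0.0, self.data)

        def backward(g):
            self._accumulate(g * _sigmoid(self.data))

        return self._make(out_data, (self,), backward)

    def softmax_last(self) -> "Tensor":
        """Row-wise softmax over the last axis."""
        shifted = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=-1, keepdims=True)

        def backward(g):
            dot = (g * out_data).sum(axis=-1, keepdims=True)
            self._accumulate(out_data * (g - dot))

        return self._make(out_data, (self,), backward)

    # -- reductions -------------------------------------------------------

    def sum(self) -> "Tensor":
        def backward(g):
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return self._make(self.data.sum(), (self,), backward)

    def mean(self, axis: int | None = None) -> "Tensor":
        if axis is None:
            n = self.data.size
            out_data = self.data.mean()

            def backward(g):
                self._accumulate(np.broadcast_to(g / n, self.shape).copy())
        else:
            n = self.data.shape[axis]
            out_data = self.data.mean(axis=axis)

            def backward(g):
                self._accumulate(np.broadcast_to(
                    np.expand_dims(g / n, axis), self.shape).copy())

        return self._make(out_data, (self,), backward)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return expit(x)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Stack tensors along a new axis."""
    data = np.stack([t.data for t in tensors], axis=axis)
    out = Tensor(data)
    parents = tuple(t for t in tensors if t.requires_grad)
    if parents:
        out.requires_grad = True
        out._prev = parents

        def backward(g):
            pieces = np.moveaxis(g, axis, 0)
            for t, piece in zip(tensors, pieces):
                if t.requires_grad:
                    t._accumulate(piece)

        out._backward = backward
    return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along an existing axis."""
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data)
    parents = tuple(t for t in tensors if t.requires_grad)
    if parents:
        out.requires_grad = True
        out._prev = parents
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def backward(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    idx = [slice(None)] * g.ndim
                    idx[axis] = slice(lo, hi)
                    t._accumulate(g[tuple(idx)])

        out._backward = backward
    return out
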