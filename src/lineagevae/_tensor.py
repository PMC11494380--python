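"""Minimal reverse-mode automatic differentiation on numpy arrays.

The model's objective (a lineage-wise evidence lower bound assembled from
Gaussian transition densities, Poisson likelihoods and mixture log-densities,
evaluated along sampled backward chains) needs gradients with respect to the
weights of three small neural networks and a handful of scalar parameters.
This module provides just the operations that objective is built from: a
:class:`Tensor` wrapping a float64 array, broadcasting-aware arithmetic,
matmul, reductions, the usual pointwise transcendentals, ``logsumexp`` and a
gradient-transparent lower clamp.  Gradients are accumulated by a topological
sweep over the recorded tape.

All operations are pure numpy and single-threaded-deterministic; every op has
a finite-difference check in the test suite.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

__all__ = ["Tensor", "concatenate", "logsumexp"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` by summing over broadcast axes."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the autodiff graph holding a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node (must be scalar if ``grad`` omitted)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
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
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64).reshape(self.data.shape)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = _make(self.data + other.data, (self, other))
        def backward(g):
            self._accumulate(_unbroadcast(g, self.shape))
            other._accumulate(_unbroadcast(g, other.shape))
        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _make(-self.data, (self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = _make(self.data * other.data, (self, other))
        def backward(g):
            self._accumulate(_unbroadcast(g * other.data, self.shape))
            other._accumulate(_unbroadcast(g * self.data, other.shape))
        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = _make(self.data / other.data, (self, other))
        def backward(g):
            self._accumulate(_unbroadcast(g / other.data, self.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / other.data**2, other.shape)
            )
        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out = _make(self.data**exponent, (self,))
        out._backward = lambda g: self._accumulate(
            g * exponent * self.data ** (exponent - 1)
        )
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = _make(self.data @ other.data, (self, other))
        def backward(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)
        out._backward = backward
        return out

    def __getitem__(self, idx):
        out = _make(self.data[idx], (self,))
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)
        out._backward = backward
        return out

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())
        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def reshape(self, *shape):
        out = _make(self.data.reshape(*shape), (self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.shape))
        return out

    # -- pointwise ---------------------------------------------------------
    def exp(self):
        val = np.exp(self.data)
        out = _make(val, (self,))
        out._backward = lambda g: self._accumulate(g * val)
        return out

    def log(self):
        out = _make(np.log(self.data), (self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def sqrt(self):
        val = np.sqrt(self.data)
        out = _make(val, (self,))
        out._backward = lambda g: self._accumulate(g * 0.5 / val)
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = _make(val, (self,))
        out._backward = lambda g: self._accumulate(g * (1.0 - val**2))
        return out

    def relu(self):
        mask = self.data > 0
        out = _make(self.data * mask, (self,))
        out._backward = lambda g: self._accumulate(g * mask)
        return out

    def softplus(self):
        # numerically stable: log(1 + exp(x)) = max(x, 0) + log1p(exp(-|x|))
        x = self.data
        val = np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))
        out = _make(val, (self,))
        sig = 1.0 / (1.0 + np.exp(-x))
        out._backward = lambda g: self._accumulate(g * sig)
        return out

    def clip_min(self, lo: float):
        """Elementwise max(self, lo); gradient is zero where clamped."""
        mask = self.data > lo
        out = _make(np.where(mask, self.data, lo), (self,))
        out._backward = lambda g: self._accumulate(g * mask)
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: tuple[Tensor, ...]) -> Tensor:
    out = Tensor(data)
    out.requires_grad = any(p.requires_grad or p._parents for p in parents)
    if out.requires_grad:
        out._parents = parents
    return out


def concatenate(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)
    out._backward = backward
    return out


def logsumexp(t: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    """Stable log-sum-exp along ``axis`` with exact gradients."""
    x = t.data
    xmax = x.max(axis=axis, keepdims=True)
    val = np.log(np.exp(x - xmax).sum(axis=axis, keepdims=True)) + xmax
    softmax = np.exp(x - val)
    if not keepdims:
        val = np.squeeze(val, axis=axis)
    out = _make(val, (t,))
    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axis)
        t._accumulate(g * softmax)
    out._backward = backward
    return out
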