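"""Minimal reverse-mode automatic differentiation over numpy arrays.

The encoder and the joint training loss are differentiated with this module.
It implements exactly the operations the network needs (dense products,
gated-recurrent-unit nonlinearities, masked softmax building blocks) as a
dynamically built computation graph of :class:`Tensor` nodes; gradients are
accumulated by a single reverse topological sweep.  All arithmetic is float64
and single-threaded, which is what makes seeded runs bit-reproducible.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

__all__ = ["Tensor", "concat", "stack_rows"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph holding a float64 array and its gradient."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple["Tensor", ...] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Run reverse-mode accumulation from this node."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs are deep for long token sequences
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
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.data + other.data, True, (self, other))

        def bw(g):
            self._accumulate(g)
            other._accumulate(g)
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, True, (self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-self._wrap(other))

    def __rsub__(self, other) -> "Tensor":
        return self._wrap(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.data * other.data, True, (self, other))

        def bw(g):
            self._accumulate(g * other.data)
            other._accumulate(g * self.data)
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.data / other.data, True, (self, other))

        def bw(g):
            self._accumulate(g / other.data)
            other._accumulate(-g * self.data / (other.data ** 2))
        out._backward = bw
        return out

    def __matmul__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, True, (self, other))

        def bw(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)
        out._backward = bw
        return out

    # -- nonlinearities ----------------------------------------------------

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, True, (self,))
        out._backward = lambda g: self._accumulate(g * s * (1.0 - s))
        return out

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)
        out = Tensor(t, True, (self,))
        out._backward = lambda g: self._accumulate(g * (1.0 - t * t))
        return out

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), True, (self,))
        out._backward = lambda g: self._accumulate(g * (self.data > 0.0))
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        out = Tensor(e, True, (self,))
        out._backward = lambda g: self._accumulate(g * e)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), True, (self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    # -- reductions and shaping -------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), True, (self,))

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))
        out._backward = bw
        return out

    def softmax_rows(self) -> "Tensor":
        """Row-wise softmax of a 2-D tensor (shift-invariant, numerically safe)."""
        z = self.data - self.data.max(axis=1, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=1, keepdims=True)
        out = Tensor(s, True, (self,))

        def bw(g):
            # J^T g for each row of the softmax Jacobian
            dot = (g * s).sum(axis=1, keepdims=True)
            self._accumulate(s * (g - dot))
        out._backward = bw
        return out


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    """Concatenate tensors along `axis`, routing gradients back to each slice."""
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 True, tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accumulate(g[tuple(idx)])
    out._backward = bw
    return out


def _as_row(t: Tensor) -> Tensor:
    if t.data.ndim == 2:
        return t
    out = Tensor(t.data.reshape(1, -1), True, (t,))
    out._backward = lambda g: t._accumulate(g.reshape(t.data.shape))
    return out


def stack_rows(tensors: Iterable[Tensor]) -> Tensor:
    """Stack 1-D or (1, d) tensors into a 2-D tensor, one per row."""
    return concat([_as_row(t) for t in tensors], axis=0)
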