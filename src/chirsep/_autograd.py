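"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the dual-graph network and its composite
loss need: affine maps, ReLU, elementwise arithmetic, row gather and
segment (scatter-add) sums.  Gradients are accumulated on leaf tensors
marked ``requires_grad``; ``backward`` walks the tape in reverse
topological order.

The ReLU subgradient at 0 is taken to be 0, and ``|x|`` built from two
ReLUs inherits that convention, so every loss in this package has finite
gradients everywhere.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "relu", "gather", "segment_sum", "matmul"]


class Tensor:
    """A numpy array plus a gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # -- graph bookkeeping -------------------------------------------------

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data)
        out._parents = (self, other)

        def _bw(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data)
        out._parents = (self,)
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data)
        out._parents = (self, other)

        def _bw(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def sum(self):
        out = Tensor(self.data.sum())
        out._parents = (self,)
        out._backward = lambda g: self._accumulate(np.broadcast_to(g, self.data.shape).copy())
        return out

    def mean(self):
        n = self.data.size
        return self.sum() * (1.0 / n)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data @ b.data)
    out._parents = (a, b)

    def _bw(g):
        a._accumulate(g @ b.data.T)
        b._accumulate(a.data.T @ g)

    out._backward = _bw
    return out


def relu(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    mask = x.data > 0
    out = Tensor(np.where(mask, x.data, 0.0))
    out._parents = (x,)
    out._backward = lambda g: x._accumulate(g * mask)
    return out


def gather(x: Tensor, index: np.ndarray) -> Tensor:
    """Select rows ``x[index]``; backward scatter-adds into the source."""
    x = _as_tensor(x)
    index = np.asarray(index, dtype=np.int64)
    out = Tensor(x.data[index])
    out._parents = (x,)

    def _bw(g):
        acc = np.zeros_like(x.data)
        np.add.at(acc, index, g)
        x._accumulate(acc)

    out._backward = _bw
    return out


def segment_sum(x: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``num_segments`` buckets (message aggregation)."""
    x = _as_tensor(x)
    segment_ids = np.asarray(segment_ids, dtype=np.int64)
    out_data = np.zeros((num_segments,) + x.data.shape[1:])
    np.add.at(out_data, segment_ids, x.data)
    out = Tensor(out_data)
    out._parents = (x,)
    out._backward = lambda g: x._accumulate(g[segment_ids])
    return out
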