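"""Reverse-mode automatic differentiation over numpy arrays.

The segmentation network needs gradients for a small, fixed set of array
operations (broadcast arithmetic, batched matmul, ReLU, axis reductions,
gather/scatter for neighbor indexing, reshapes and concatenation).  This
module provides a :class:`Tensor` wrapping an ``ndarray`` together with a
tape of those operations; :meth:`Tensor.backward` walks the tape in reverse
topological order and accumulates gradients.

Gradient correctness is established against central finite differences in
the test suite; every primitive here is covered by that check.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "gather_neighbors", "log_softmax", "relu"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that numpy broadcasting introduced."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ``ndarray`` with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad: np.ndarray | None = None):
        """Backpropagate from this tensor through the recorded tape."""
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: the tape can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = _result(self.data + other.data, (self, other))
        if out.requires_grad:
            def bw(g, a=self, b=other):
                if a.requires_grad:
                    a._accumulate(_unbroadcast(g, a.shape))
                if b.requires_grad:
                    b._accumulate(_unbroadcast(g, b.shape))
            out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _result(-self.data, (self,))
        if out.requires_grad:
            def bw(g, a=self):
                a._accumulate(-g)
            out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = _result(self.data * other.data, (self, other))
        if out.requires_grad:
            def bw(g, a=self, b=other):
                if a.requires_grad:
                    a._accumulate(_unbroadcast(g * b.data, a.shape))
                if b.requires_grad:
                    b._accumulate(_unbroadcast(g * a.data, b.shape))
            out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * (as_tensor(other) ** -1.0)

    def __rtruediv__(self, other):
        return as_tensor(other) * (self ** -1.0)

    def __pow__(self, p: float):
        out = _result(self.data ** p, (self,))
        if out.requires_grad:
            def bw(g, a=self):
                a._accumulate(g * p * a.data ** (p - 1.0))
            out._backward = bw
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = _result(self.data @ other.data, (self, other))
        if out.requires_grad:
            def bw(g, a=self, b=other):
                if a.requires_grad:
                    ga = g @ np.swapaxes(b.data, -1, -2) if b.ndim > 1 else \
                        np.expand_dims(g, -1) * b.data
                    a._accumulate(_unbroadcast(ga, a.shape))
                if b.requires_grad:
                    gb = np.swapaxes(a.data, -1, -2) @ g if a.ndim > 1 else \
                        np.expand_dims(a.data, -1) * np.expand_dims(g, -2)
                    b._accumulate(_unbroadcast(gb, b.shape))
            out._backward = bw
        return out

    # -- unary / reductions ----------------------------------------------
    def exp(self):
        out = _result(np.exp(self.data), (self,))
        if out.requires_grad:
            def bw(g, a=self, v=out.data):
                a._accumulate(g * v)
            out._backward = bw
        return out

    def log(self):
        out = _result(np.log(self.data), (self,))
        if out.requires_grad:
            def bw(g, a=self):
                a._accumulate(g / a.data)
            out._backward = bw
        return out

    def sum(self, axis=None, keepdims=False):
        out = _result(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out.requires_grad:
            def bw(g, a=self):
                gg = g
                if axis is not None and not keepdims:
                    gg = np.expand_dims(gg, axis)
                a._accumulate(np.broadcast_to(gg, a.shape).copy())
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        """Maximum along ``axis``; the gradient flows to the first argmax."""
        idx = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(idx, axis),
                                      axis=axis)
        if not keepdims:
            out_data = np.squeeze(out_data, axis=axis)
        out = _result(out_data, (self,))
        if out.requires_grad:
            def bw(g, a=self):
                gg = g if keepdims else np.expand_dims(g, axis)
                ga = np.zeros_like(a.data)
                np.put_along_axis(ga, np.expand_dims(idx, axis), gg, axis=axis)
                a._accumulate(ga)
            out._backward = bw
        return out

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        out = _result(self.data.reshape(*shape), (self,))
        if out.requires_grad:
            def bw(g, a=self):
                a._accumulate(g.reshape(a.shape))
            out._backward = bw
        return out

    def swapaxes(self, a1: int, a2: int):
        out = _result(np.swapaxes(self.data, a1, a2), (self,))
        if out.requires_grad:
            def bw(g, a=self):
                a._accumulate(np.swapaxes(g, a1, a2))
            out._backward = bw
        return out

    @property
    def T(self):
        return self.swapaxes(-1, -2)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _result(data: np.ndarray, parents: tuple[Tensor, ...]) -> Tensor:
    out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
    if out.requires_grad:
        out._prev = tuple(p for p in parents if isinstance(p, Tensor))
    return out


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0
    out = _result(np.where(mask, x.data, 0.0), (x,))
    if out.requires_grad:
        def bw(g, a=x):
            a._accumulate(np.where(mask, g, 0.0))
        out._backward = bw
    return out


def concatenate(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _result(np.concatenate([t.data for t in tensors], axis=axis),
                  tuple(tensors))
    if out.requires_grad:
        sizes = [t.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bw(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accumulate(piece)
        out._backward = bw
    return out


def gather_neighbors(x: Tensor, idx: np.ndarray) -> Tensor:
    """Gather per-point neighbor features.

    ``x`` is ``(N, C)`` or ``(B, N, C)``; ``idx`` is ``(N, K)`` or
    ``(B, N, K)`` of point indices into the N axis.  Returns
    ``(N, K, C)`` / ``(B, N, K, C)``.  The backward pass scatter-adds.
    """
    x = as_tensor(x)
    idx = np.asarray(idx)
    if x.ndim == 2:
        out_data = x.data[idx]                     # (N, K, C)
        out = _result(out_data, (x,))
        if out.requires_grad:
            def bw(g, a=x):
                ga = np.zeros_like(a.data)
                np.add.at(ga, idx.ravel(), g.reshape(-1, a.shape[-1]))
                a._accumulate(ga)
            out._backward = bw
        return out
    if x.ndim == 3:
        b = np.arange(x.shape[0])[:, None, None]
        out_data = x.data[b, idx]                  # (B, N, K, C)
        out = _result(out_data, (x,))
        if out.requires_grad:
            def bw(g, a=x):
                ga = np.zeros_like(a.data)
                np.add.at(ga, (np.broadcast_to(b, idx.shape), idx), g)
                a._accumulate(ga)
            out._backward = bw
        return out
    raise ValueError(f"gather_neighbors expects 2-D or 3-D input, got {x.ndim}-D")


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable log-softmax with an analytic backward pass."""
    x = as_tensor(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out_data = shifted - lse
    out = _result(out_data, (x,))
    if out.requires_grad:
        softmax = np.exp(out_data)

        def bw(g, a=x):
            a._accumulate(g - softmax * g.sum(axis=axis, keepdims=True))
        out._backward = bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    return log_softmax(x, axis=axis).exp()
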