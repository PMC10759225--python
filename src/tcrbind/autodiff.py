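"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the cross-attention network needs: broadcast
arithmetic, batched matmul, exp/log/pow, relu/sigmoid/tanh, reductions,
reshape/transpose/concatenate, embedding lookup and a numerically stable
masked softmax.  Gradients flow through a tape built dynamically; call
``backward()`` on a scalar Tensor.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "softmax", "concatenate", "embedding"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- tape plumbing ---------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ------------------------------------------------------

    def _binary(self, other, fwd, bwd_self, bwd_other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(fwd(self.data, other.data),
                     self.requires_grad or other.requires_grad)
        if out.requires_grad:
            out._prev = (self, other)

            def _backward(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(bwd_self(g), self.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(bwd_other(g), other.shape))
            out._backward = _backward
        return out

    def __add__(self, other):
        return self._binary(other, np.add, lambda g: g, lambda g: g)

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, np.subtract, lambda g: g, lambda g: -g)

    def __rsub__(self, other):
        return self._lift(other) - self

    def __mul__(self, other):
        other = self._lift(other)
        return self._binary(other, np.multiply,
                            lambda g: g * other.data, lambda g: g * self.data)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._lift(other) ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __neg__(self):
        return self * -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad)
        if out.requires_grad:
            out._prev = (self,)
            out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad)
        if out.requires_grad:
            out._prev = (self, other)

            def _backward(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(
                        g @ np.swapaxes(other.data, -1, -2), self.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(
                        np.swapaxes(self.data, -1, -2) @ g, other.shape))
            out._backward = _backward
        return out

    # -- elementwise nonlinearities --------------------------------------

    def exp(self):
        out = Tensor(np.exp(self.data), self.requires_grad)
        if out.requires_grad:
            out._prev = (self,)
            out._backward = lambda g: self._accum(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad)
        if out.requires_grad:
            out._prev = (self,)
            out._backward = lambda g: self._accum(g / self.data)
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad)
        if out.requires_grad:
            out._prev = (self,)
            out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, self.requires_grad)
        if out.requires_grad:
            out._prev = (self,)
            out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, self.requires_grad)
        if out.requires_grad:
            out._prev = (self,)
            out._backward = lambda g: self._accum(g * (1.0 - t * t))
        return out

    # -- reductions and shape ops ----------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad)
        if out.requires_grad:
            out._prev = (self,)

            def _backward(g):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.shape).copy())
            out._backward = _backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad)
        if out.requires_grad:
            out._prev = (self,)
            out._backward = lambda g: self._accum(g.reshape(self.shape))
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), self.requires_grad)
        if out.requires_grad:
            inv = np.argsort(axes)
            out._prev = (self,)
            out._backward = lambda g: self._accum(g.transpose(*inv))
        return out

    def swapaxes(self, a, b):
        out = Tensor(np.swapaxes(self.data, a, b), self.requires_grad)
        if out.requires_grad:
            out._prev = (self,)
            out._backward = lambda g: self._accum(np.swapaxes(g, a, b))
        return out


def softmax(x: Tensor, axis: int = -1, mask: np.ndarray | None = None) -> Tensor:
    """Numerically stable softmax along ``axis``.

    ``mask`` is a boolean array (broadcastable to x.shape); False positions get
    zero probability.  The max-shift is treated as a constant, which yields the
    exact gradient because softmax is invariant under uniform shifts.
    """
    data = x.data
    if mask is not None:
        neg = np.where(mask, 0.0, -1e30)
        x = x + neg
        data = x.data
    shift = data.max(axis=axis, keepdims=True)
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def concatenate(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis),
                 any(t.requires_grad for t in tensors))
    if out.requires_grad:
        out._prev = tuple(tensors)
        sizes = [d.shape[axis] for d in datas]
        offsets = np.cumsum([0] + sizes)

        def _backward(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    t._accum(g[tuple(sl)])
        out._backward = _backward
    return out


def embedding(weight: Tensor, indices: np.ndarray) -> Tensor:
    """Row lookup ``weight[indices]`` with scatter-add backward."""
    idx = np.asarray(indices)
    out = Tensor(weight.data[idx], weight.requires_grad)
    if out.requires_grad:
        out._prev = (weight,)

        def _backward(g):
            acc = np.zeros_like(weight.data)
            np.add.at(acc, idx.reshape(-1),
                      g.reshape(-1, weight.data.shape[-1]))
            weight._accum(acc)
        out._backward = _backward
    return out
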