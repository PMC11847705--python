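"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` walks the recorded graph in reverse topological
order and accumulates gradients into every tensor created with
``requires_grad=True``. Only the operations the network layers need are
implemented; all of them support numpy broadcasting, with gradients reduced
back to the operand's shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that were broadcast to reach its shape."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes of size 1 expanded by broadcasting
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------

    @classmethod
    def _node(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad or p._parents for p in parents):
            out._parents = tuple(parents)
            out._backward = backward
            out.requires_grad = True
        return out

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can exceed the recursion limit
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        def backward(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))
        return Tensor._node(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)
        return Tensor._node(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))
        return Tensor._node(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        def backward(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(_unbroadcast(-g * self.data / other.data**2,
                                      other.data.shape))
        return Tensor._node(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p: float):
        def backward(g):
            self._accum(g * p * self.data ** (p - 1))
        return Tensor._node(self.data**p, (self,), backward)

    def __matmul__(self, other):
        other = _as_tensor(other)
        def backward(g):
            a, b = self.data, other.data
            if b.ndim == 1:
                ga = np.multiply.outer(g, b) if a.ndim > 1 else g[..., None] * b
                gb = np.tensordot(g, a, axes=(range(g.ndim), range(g.ndim)))
                self._accum(_unbroadcast(ga.reshape(a.shape), a.shape))
                other._accum(gb)
                return
            ga = g @ b.swapaxes(-1, -2) if a.ndim > 1 else g @ b.T
            gb = (a.swapaxes(-1, -2) @ g) if a.ndim > 1 else np.outer(a, g)
            self._accum(_unbroadcast(ga, a.shape))
            other._accum(_unbroadcast(gb, b.shape))
        return Tensor._node(self.data @ other.data, (self, other), backward)

    # -- elementwise nonlinearities ---------------------------------------

    def exp(self):
        out_data = np.exp(self.data)
        def backward(g):
            self._accum(g * out_data)
        return Tensor._node(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)
        return Tensor._node(np.log(self.data), (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)
        def backward(g):
            self._accum(g * (1.0 - out_data**2))
        return Tensor._node(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))
        return Tensor._node(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0
        def backward(g):
            self._accum(g * mask)
        return Tensor._node(self.data * mask, (self,), backward)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only through unclamped entries."""
        mask = (self.data > lo) & (self.data < hi)
        def backward(g):
            self._accum(g * mask)
        return Tensor._node(np.clip(self.data, lo, hi), (self,), backward)

    # -- reductions & shape ------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())
        return Tensor._node(self.data.sum(axis=axis, keepdims=keepdims),
                            (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        orig = self.data.shape
        def backward(g):
            self._accum(g.reshape(orig))
        return Tensor._node(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)
        def backward(g):
            self._accum(g.transpose(inv))
        return Tensor._node(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        def backward(g):
            gd = np.zeros_like(self.data)
            np.add.at(gd, idx, g)
            self._accum(gd)
        return Tensor._node(self.data[idx], (self,), backward)

    def take_rows(self, idx: np.ndarray):
        """Row gather (embedding lookup); duplicates accumulate on backward."""
        idx = np.asarray(idx)
        def backward(g):
            gd = np.zeros_like(self.data)
            np.add.at(gd, idx, g)
            self._accum(gd)
        return Tensor._node(self.data[idx], (self,), backward)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        def backward(g):
            self._accum(s * (g - (g * s).sum(axis=axis, keepdims=True)))
        return Tensor._node(s, (self,), backward)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accum(g[tuple(sl)])
    return Tensor._node(np.concatenate([t.data for t in tensors], axis=axis),
                        tensors, backward)
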