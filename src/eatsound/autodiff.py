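"""Minimal reverse-mode automatic differentiation over numpy arrays.

A deliberately small tensor engine: enough broadcasting, matmul, slicing and
pointwise ops to express recurrent encoders, additive attention and sequence
losses, with float64 throughout for numerically tight loss values.  Graphs are
built eagerly; ``Tensor.backward()`` runs a topological sweep and accumulates
gradients into every tensor created with ``requires_grad=True``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "parameter", "constant", "concat", "stack", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_bw")

    def __init__(self, data, requires_grad=False, parents=(), bw=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._bw = bw

    # -- helpers ----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _acc(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bw(g):
            if self.requires_grad:
                self._acc(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._acc(_unbroadcast(g, other.data.shape))
        out._bw = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        out._bw = lambda g: self.requires_grad and self._acc(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bw(g):
            if self.requires_grad:
                self._acc(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._acc(_unbroadcast(g * self.data, other.data.shape))
        out._bw = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise TypeError("divide by a Tensor is unsupported; multiply by a reciprocal")
        return self * (1.0 / other)

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._acc(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._acc(_unbroadcast(gb, other.data.shape))
        out._bw = bw
        return out

    # -- pointwise --------------------------------------------------------
    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, self.requires_grad, (self,))
        out._bw = lambda g: self.requires_grad and self._acc(g * (1.0 - y * y))
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(y, self.requires_grad, (self,))
        out._bw = lambda g: self.requires_grad and self._acc(g * y * (1.0 - y))
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, self.requires_grad, (self,))
        out._bw = lambda g: self.requires_grad and self._acc(g * y)
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        out._bw = lambda g: self.requires_grad and self._acc(g / self.data)
        return out

    # -- shape ------------------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))
        out._bw = lambda g: self.requires_grad and self._acc(g.reshape(self.data.shape))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._acc(full)
        out._bw = bw
        return out

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._acc(np.broadcast_to(g, self.data.shape).copy())
            else:
                ge = g if keepdims else np.expand_dims(g, axis)
                self._acc(np.broadcast_to(ge, self.data.shape).copy())
        out._bw = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def log_softmax(self, axis=-1):
        m = self.data.max(axis=axis, keepdims=True)
        z = self.data - m
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True)) + m
        y = self.data - lse
        out = Tensor(y, self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._acc(g - np.exp(y) * g.sum(axis=axis, keepdims=True))
        out._bw = bw
        return out

    def softmax(self, axis=-1):
        return self.log_softmax(axis=axis).exp()

    # -- autodiff ---------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo, seen = [], set()
        stack = [self]
        while stack:  # iterative post-order DFS
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node._parents
                         if id(p) not in seen and p.requires_grad]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                stack.pop()
                topo.append(node)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._bw is not None and node.grad is not None:
                node._bw(node.grad)

    def item(self) -> float:
        return float(self.data)


def parameter(data) -> Tensor:
    return Tensor(np.array(data, dtype=np.float64), requires_grad=True)


def constant(data) -> Tensor:
    return Tensor(data)


def concat(tensors, axis=-1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._acc(piece)
    out._bw = bw
    return out


def stack(tensors, axis=0) -> Tensor:
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))

    def bw(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._acc(np.take(g, i, axis=axis))
    out._bw = bw
    return out


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def clip_grad_norm(self, max_norm: float) -> float:
        total = np.sqrt(sum(float((p.grad ** 2).sum())
                            for p in self.params if p.grad is not None))
        if total > max_norm and total > 0:
            scale = max_norm / total
            for p in self.params:
                if p.grad is not None:
                    p.grad *= scale
        return total

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
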