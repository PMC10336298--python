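"""Minimal reverse-mode automatic differentiation on numpy arrays.

Only the operations the encoder needs are provided: broadcast arithmetic,
(batched) matrix products, ReLU, a numerically stable softmax, layer
normalization, embedding-row gathering, concatenation, dropout and reductions.
Gradients flow through a dynamically recorded tape; ``Tensor.backward`` walks
the tape in reverse topological order. Everything is float64, which keeps the
finite-difference gradient checks in the test suite tight.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "gather_rows", "softmax", "layer_norm", "relu", "dropout"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape``, undoing numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # -- bookkeeping ------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64, copy=True)
        else:
            self.grad += grad

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient needs a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS, deep graphs must not hit the recursion limit
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor(self.data + other.data, parents=(self, other), backward=bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor(-self.data, parents=(self,), backward=bw)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor(self.data * other.data, parents=(self, other), backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g * self.data / other.data**2, other.shape))

        return Tensor(self.data / other.data, parents=(self, other), backward=bw)

    def __matmul__(self, other):
        other = self._lift(other)

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))

        return Tensor(self.data @ other.data, parents=(self, other), backward=bw)

    # -- shape ops --------------------------------------------------------

    def reshape(self, *shape):
        old = self.shape

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old))

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=bw)

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        return Tensor(self.data.transpose(axes), parents=(self,), backward=bw)

    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
            else:
                ge = np.expand_dims(g, axis) if not keepdims else g
                self._accumulate(np.broadcast_to(ge, self.shape).copy())

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,), backward=bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bw(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor(np.where(mask, x.data, 0.0), parents=(x,), backward=bw)


def softmax(x: Tensor, additive_mask: np.ndarray | None = None) -> Tensor:
    """Softmax over the last axis; ``additive_mask`` is added to the scores
    before normalization (use large negatives to exclude padding keys)."""
    scores = x.data if additive_mask is None else x.data + additive_mask
    shifted = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    out = e / e.sum(axis=-1, keepdims=True)

    def bw(g):
        if x.requires_grad:
            dot = (g * out).sum(axis=-1, keepdims=True)
            x._accumulate(out * (g - dot))

    return Tensor(out, parents=(x,), backward=bw)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize the last axis to zero mean / unit variance, then scale-shift."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc**2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    d = x.data.shape[-1]

    def bw(g):
        if gamma.requires_grad:
            gamma._accumulate(_unbroadcast(g * xhat, gamma.shape))
        if beta.requires_grad:
            beta._accumulate(_unbroadcast(g, beta.shape))
        if x.requires_grad:
            gx = g * gamma.data
            t1 = gx.sum(axis=-1, keepdims=True)
            t2 = (gx * xhat).sum(axis=-1, keepdims=True)
            x._accumulate(inv / d * (d * gx - t1 - xhat * t2))

    return Tensor(xhat * gamma.data + beta.data, parents=(x, gamma, beta), backward=bw)


def gather_rows(table: Tensor, indices: np.ndarray) -> Tensor:
    """Embedding lookup: rows of ``table`` selected by an integer array."""
    idx = np.asarray(indices)

    def bw(g):
        if table.requires_grad:
            acc = np.zeros_like(table.data)
            np.add.at(acc, idx.reshape(-1), g.reshape(-1, table.data.shape[-1]))
            table._accumulate(acc)

    return Tensor(table.data[idx], parents=(table,), backward=bw)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    return Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors), backward=bw)


def dropout(x: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity when ``rng`` is None (inference) or rate 0."""
    if rng is None or rate <= 0.0:
        return x
    keep = rng.random(x.shape) >= rate
    scale = 1.0 / (1.0 - rate)

    def bw(g):
        if x.requires_grad:
            x._accumulate(g * keep * scale)

    return Tensor(x.data * keep * scale, parents=(x,), backward=bw)
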