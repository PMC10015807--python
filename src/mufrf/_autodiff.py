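"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the model needs: broadcast arithmetic,
(batched) matrix products, elementwise nonlinearities, reductions,
reshaping/transposition, concatenation, row gathering and window
extraction (``take``).  Gradients accumulate in ``Tensor.grad`` after
calling :meth:`Tensor.backward` on a scalar.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "logsigmoid", "softmax", "log_softmax", "layer_norm"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    # -- graph plumbing -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _make(self, data, parents, backward):
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)

        def bwd(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g, other.shape)

        return self._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            if self.requires_grad:
                self.grad += -g

        return self._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)

        def bwd(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * other.data, self.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * self.data, other.shape)

        return self._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * _as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return _as_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        # constant exponent only
        out_data = self.data ** exponent

        def bwd(g):
            if self.requires_grad:
                self.grad += g * exponent * self.data ** (exponent - 1.0)

        return self._make(out_data, (self,), bwd)

    def __matmul__(self, other):
        other = _as_tensor(other)
        a, b = self.data, other.data

        def bwd(g):
            if self.requires_grad:
                if b.ndim == 2:
                    self.grad += _unbroadcast(g @ b.T, self.shape)
                else:
                    self.grad += _unbroadcast(g @ np.swapaxes(b, -1, -2), self.shape)
            if other.requires_grad:
                if a.ndim == 2 and b.ndim == 2:
                    other.grad += a.T @ g
                elif b.ndim == 2:
                    # batched a @ 2-D b: accumulate over batch
                    k, n = b.shape
                    other.grad += a.reshape(-1, k).T @ g.reshape(-1, n)
                else:
                    other.grad += _unbroadcast(np.swapaxes(a, -1, -2) @ g, other.shape)

        return self._make(a @ b, (self, other), bwd)

    # -- elementwise ----------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def bwd(g):
            if self.requires_grad:
                self.grad += g * mask

        return self._make(self.data * mask, (self,), bwd)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))

        def bwd(g):
            if self.requires_grad:
                self.grad += g * s * (1.0 - s)

        return self._make(s, (self,), bwd)

    def exp(self):
        e = np.exp(self.data)

        def bwd(g):
            if self.requires_grad:
                self.grad += g * e

        return self._make(e, (self,), bwd)

    def log(self):
        def bwd(g):
            if self.requires_grad:
                self.grad += g / self.data

        return self._make(np.log(self.data), (self,), bwd)

    def sqrt(self):
        return self ** 0.5

    def cos(self):
        def bwd(g):
            if self.requires_grad:
                self.grad += -g * np.sin(self.data)

        return self._make(np.cos(self.data), (self,), bwd)

    def sin(self):
        def bwd(g):
            if self.requires_grad:
                self.grad += g * np.cos(self.data)

        return self._make(np.sin(self.data), (self,), bwd)

    def tanh(self):
        t = np.tanh(self.data)

        def bwd(g):
            if self.requires_grad:
                self.grad += g * (1.0 - t * t)

        return self._make(t, (self,), bwd)

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self.grad += np.broadcast_to(g, self.shape)
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self.grad += np.broadcast_to(g, self.shape)

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ----------------------------------------------------------
    def reshape(self, *shape):
        old = self.shape

        def bwd(g):
            if self.requires_grad:
                self.grad += g.reshape(old)

        return self._make(self.data.reshape(*shape), (self,), bwd)

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)

        def bwd(g):
            if self.requires_grad:
                self.grad += g.transpose(inv)

        return self._make(self.data.transpose(axes), (self,), bwd)

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, key):
        def bwd(g):
            if self.requires_grad:
                np.add.at(self.grad, key, g)

        return self._make(self.data[key], (self,), bwd)

    def gather_rows(self, indices: np.ndarray):
        """Select rows by integer index (with repetition); scatter-adds on backward."""
        indices = np.asarray(indices, dtype=np.intp)

        def bwd(g):
            if self.requires_grad:
                np.add.at(self.grad, indices, g)

        return self._make(self.data[indices], (self,), bwd)

    def take(self, indices: np.ndarray, axis: int):
        """np.take along ``axis`` with an arbitrary-shape index array."""
        indices = np.asarray(indices, dtype=np.intp)
        out_data = np.take(self.data, indices, axis=axis)
        ax = axis % self.ndim

        def bwd(g):
            if self.requires_grad:
                idx = (slice(None),) * ax + (indices,)
                np.add.at(self.grad, idx, g)

        return self._make(out_data, (self,), bwd)


# -- composites ---------------------------------------------------------

def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    out = Tensor(data)
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        out._parents = tuple(tensors)

        def bwd(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t.grad += piece

        out._backward = bwd
    return out


def logsigmoid(x: Tensor) -> Tensor:
    """Numerically stable log σ(x); gradient σ(−x)."""
    x = _as_tensor(x)
    d = x.data
    out_data = np.minimum(d, 0.0) - np.log1p(np.exp(-np.abs(d)))

    def bwd(g):
        if x.requires_grad:
            x.grad += g / (1.0 + np.exp(np.clip(d, -500, 500)))  # σ(−x)

    return x._make(out_data, (x,), bwd)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    return centered * (var + eps) ** -0.5 * gain + bias
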