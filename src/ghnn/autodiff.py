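"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the model needs: (batched) dense matmul,
sparse-dense matmul, broadcasting arithmetic, ReLU, softmax, layer
normalization, dropout, concatenation, indexing, reductions, and a
numerically stable binary cross-entropy on logits.  Gradients are
accumulated by topological traversal of the recorded tape.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = ["Tensor", "Parameter", "relu", "sigmoid", "softmax", "layer_norm",
           "dropout", "concat", "sparse_matmul", "bce_with_logits"]


class Tensor:
    """A numpy array plus the closure that routes gradients to its parents."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # -- graph bookkeeping -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g):
        # Copy-on-write: adopt the first contribution as-is (it may alias a
        # child's grad — never mutated afterwards), allocate on the second.
        if self.grad is None:
            self.grad = g
        else:
            self.grad = self.grad + g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(grad)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(-g)
        out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise TypeError("division by Tensor not supported; use * (1/x)")
        return self * (1.0 / other)

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.shape))
        out._backward = bw
        return out

    # -- shape ops ---------------------------------------------------------

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)
        out._backward = bw
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))
        out._backward = bw
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), parents=(self,))
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accum(g.transpose(*inv))
        out._backward = bw
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- misc --------------------------------------------------------------

    def detach(self):
        return Tensor(self.data)

    def item(self):
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"


def Parameter(data):
    """A leaf tensor tracked by the optimizer."""
    return Tensor(np.asarray(data), requires_grad=True)


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def as_float_tensor(x):
    """Wrap an array as a Tensor, preserving float32; else cast to float64."""
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x)
    return Tensor(arr if arr.dtype.kind == "f" else arr.astype(float))


def _unbroadcast(g, shape):
    """Sum gradient g down to `shape` (reverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


# -- nonlinearities ---------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0), parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accum(g * (x.data > 0))
    out._backward = bw
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    out = Tensor(s, parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accum(g * s * (1 - s))
    out._backward = bw
    return out


def softmax(x: Tensor, axis=-1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, parents=(x,))

    def bw(g):
        if x.requires_grad:
            dot = (g * s).sum(axis=axis, keepdims=True)
            x._accum(s * (g - dot))
    out._backward = bw
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps=1e-5) -> Tensor:
    """Normalization over the last axis with learned scale and shift."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = Tensor(xhat * gamma.data + beta.data, parents=(x, gamma, beta))

    def bw(g):
        if gamma.requires_grad:
            gamma._accum(_unbroadcast(g * xhat, gamma.shape))
        if beta.requires_grad:
            beta._accum(_unbroadcast(g, beta.shape))
        if x.requires_grad:
            gx = g * gamma.data
            t1 = gx - gx.mean(axis=-1, keepdims=True)
            t2 = xhat * (gx * xhat).mean(axis=-1, keepdims=True)
            x._accum(inv * (t1 - t2))
    out._backward = bw
    return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator,
            train_mode: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate is 0."""
    if not train_mode or rate <= 0:
        return x
    keep = 1.0 - rate
    u = rng.random(x.shape, dtype=np.float32) if x.data.dtype == np.float32 \
        else rng.random(x.shape)
    mask = (u < keep).astype(x.data.dtype) * np.asarray(1.0 / keep,
                                                        dtype=x.data.dtype)
    out = Tensor(x.data * mask, parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accum(g * mask)
    out._backward = bw
    return out


def concat(tensors, axis=-1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, gpart in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(gpart)
    out._backward = bw
    return out


def sparse_matmul(P: sp.spmatrix, x: Tensor) -> Tensor:
    """P @ x where P is a constant scipy sparse matrix."""
    out = Tensor(P @ x.data, parents=(x,))
    Pt = P.T.tocsr()

    def bw(g):
        if x.requires_grad:
            x._accum(Pt @ g)
    out._backward = bw
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy computed stably from logits.

    Uses the identity BCE = max(z,0) - z*y + log(1 + exp(-|z|)).
    """
    z = logits.data
    y = np.asarray(targets, dtype=z.dtype)
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    out = Tensor(np.array(loss.mean()), parents=(logits,))
    n = z.size

    def bw(g):
        if logits.requires_grad:
            s = 1.0 / (1.0 + np.exp(-z))
            logits._accum(g * (s - y) / n)
    out._backward = bw
    return out
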