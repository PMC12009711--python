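"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The package's trainable components (graph encoder, projection head,
bond-classification head, generation policy) are small dense networks; this
module provides exactly the operator set they need, with gradients verified
against finite differences in the test suite.  Sparse matrices (used for
batched message passing over block-diagonal molecular adjacency) participate
as constants via :func:`spmm`.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse as _sp

__all__ = ["Tensor", "Linear", "MLP", "Adam", "concat", "stack", "spmm"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverses NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_backward")

    def __init__(self, data, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = parents
        self._backward = backward

    # ---- graph bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    def zero_grad(self):
        self.grad = None

    # ---- arithmetic --------------------------------------------------------
    @staticmethod
    def _lift(x):
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, (self, other))

        def bw():
            self._accum(_unbroadcast(out.grad, self.data.shape))
            other._accum(_unbroadcast(out.grad, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._backward = lambda: self._accum(-out.grad)
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, (self, other))

        def bw():
            self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * (Tensor._lift(other) ** -1.0)

    def __rtruediv__(self, other):
        return Tensor._lift(other) * (self ** -1.0)

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, (self,))
        out._backward = lambda: self._accum(out.grad * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data, (self, other))

        def bw():
            self._accum(out.grad @ other.data.T)
            other._accum(self.data.T @ out.grad)

        out._backward = bw
        return out

    # ---- nonlinearities and reductions ------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), (self,))
        out._backward = lambda: self._accum(out.grad * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), (self,))
        out._backward = lambda: self._accum(out.grad / self.data)
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, (self,))
        out._backward = lambda: self._accum(out.grad * mask)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(s, (self,))
        out._backward = lambda: self._accum(out.grad * s * (1 - s))
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def clamp(self, lo: float, hi: float):
        """Clip values; gradient passes only through the unclipped region."""
        mask = (self.data >= lo) & (self.data <= hi)
        out = Tensor(np.clip(self.data, lo, hi), (self,))
        out._backward = lambda: self._accum(out.grad * mask)
        return out

    def minimum(self, other: "Tensor"):
        other = Tensor._lift(other)
        take_self = self.data <= other.data
        out = Tensor(np.where(take_self, self.data, other.data), (self, other))

        def bw():
            self._accum(out.grad * take_self)
            other._accum(out.grad * ~take_self)

        out._backward = bw
        return out

    # ---- indexing / shaping -------------------------------------------------
    def rows(self, idx):
        """Gather rows (first-axis fancy indexing, duplicates allowed)."""
        idx = np.asarray(idx, dtype=np.intp)
        out = Tensor(self.data[idx], (self,))

        def bw():
            g = np.zeros_like(self.data)
            np.add.at(g, idx, out.grad)
            self._accum(g)

        out._backward = bw
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))
        out._backward = lambda: self._accum(out.grad.reshape(self.data.shape))
        return out

    @property
    def T(self):
        out = Tensor(self.data.T, (self,))
        out._backward = lambda: self._accum(out.grad.T)
        return out

    def detach(self):
        return Tensor(self.data.copy())

    # ---- composites ---------------------------------------------------------
    def l2_normalize(self, eps: float = 1e-12):
        """Row-wise unit L2 normalization (last axis)."""
        sq = (self * self).sum(axis=-1, keepdims=True)
        return self * ((sq + eps) ** -0.5)

    def log_softmax(self):
        """Numerically stable log-softmax along the last axis."""
        shift = self - float(self.data.max())
        e = shift.exp()
        return shift - e.sum(axis=-1, keepdims=True).log()


def concat(tensors, axis=0):
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw():
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * out.grad.ndim
            sl[axis] = slice(a, b)
            t._accum(out.grad[tuple(sl)])

    out._backward = bw
    return out


def stack(tensors):
    """Stack 1-D tensors into a 2-D tensor (rows)."""
    out = Tensor(np.stack([t.data for t in tensors]), tuple(tensors))

    def bw():
        for i, t in enumerate(tensors):
            t._accum(out.grad[i])

    out._backward = bw
    return out


def spmm(a_sparse, x: Tensor) -> Tensor:
    """Sparse(const) @ dense(Tensor); the sparse factor carries no gradient."""
    a = _sp.csr_matrix(a_sparse)
    out = Tensor(a @ x.data, (x,))
    out._backward = lambda: x._accum(a.T @ out.grad)
    return out


# ---------------------------------------------------------------------------
# layers and optimizer
# ---------------------------------------------------------------------------


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True):
        scale = np.sqrt(2.0 / n_in)
        self.W = Tensor(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Tensor(np.zeros(n_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        return out + self.b if self.b is not None else out

    @property
    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])


class MLP:
    """Fully connected stack with ReLU between layers (none after the last)."""

    def __init__(self, sizes, rng: np.random.Generator, bias: bool = True):
        self.layers = [Linear(a, b, rng, bias=bias)
                       for a, b in zip(sizes[:-1], sizes[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.relu()
        return x

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]


class Adam:
    """Adam with optional decoupled weight decay and per-group learning rates.

    `groups` is a list of (params, lr) pairs.
    """

    def __init__(self, groups, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.groups = [(list(ps), float(lr)) for ps, lr in groups]
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.state = {}
        for ps, _ in self.groups:
            for p in ps:
                self.state[id(p)] = (np.zeros_like(p.data), np.zeros_like(p.data))

    def zero_grad(self):
        for ps, _ in self.groups:
            for p in ps:
                p.grad = None

    def step(self):
        self.t += 1
        for ps, lr in self.groups:
            for p in ps:
                if p.grad is None:
                    continue
                g = p.grad
                if self.weight_decay:
                    g = g + self.weight_decay * p.data
                m, v = self.state[id(p)]
                m[:] = self.b1 * m + (1 - self.b1) * g
                v[:] = self.b2 * v + (1 - self.b2) * g * g
                mhat = m / (1 - self.b1 ** self.t)
                vhat = v / (1 - self.b2 ** self.t)
                p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)
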