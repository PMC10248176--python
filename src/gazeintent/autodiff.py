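"""Minimal reverse-mode tensor autodiff on numpy.

The networks in this package are small (a few thousand trainable scalars),
so a compact tape-based engine is sufficient: every operation records a
backward closure, :meth:`Tensor.backward` walks the tape in reverse
topological order.  Only the operations the three architectures need are
implemented.  All data is kept in float64.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def param(data) -> "Tensor":
        return Tensor(data, requires_grad=True)

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd -------------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, g):
        g = _unbroadcast(g, self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    @staticmethod
    def _wrap(other):
        return other if isinstance(other, Tensor) else Tensor(other)

    def _needs(self, *others):
        return self.requires_grad or any(o.requires_grad for o in others)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, self._needs(other), (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, self._needs(other), (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        return self * (1.0 / float(scalar))

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, self._needs(other), (self, other))
        a, b = self.data, other.data

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(b, -1, -2) if b.ndim > 1 else np.outer(g, b)
                self._accum(ga)
            if other.requires_grad:
                gb = np.swapaxes(a, -1, -2) @ g if a.ndim > 1 else np.outer(a, g)
                other._accum(gb)

        out._backward = bw
        return out

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        shp = self.data.shape
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g.reshape(shp))
        return out

    def swapaxes(self, a, b):
        out = Tensor(np.swapaxes(self.data, a, b), self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(np.swapaxes(g, a, b))
        return out

    def slice(self, key):
        out = Tensor(self.data[key], self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[key] = g
                self._accum(full)

        out._backward = bw
        return out

    def __getitem__(self, key):
        return self.slice(key)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad, (self,))
        shp = self.data.shape

        def bw(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, shp))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def max(self, axis: int):
        idx = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis).squeeze(axis)
        out = Tensor(out_data, self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.put_along_axis(full, np.expand_dims(idx, axis), np.expand_dims(g, axis), axis)
                self._accum(full)

        out._backward = bw
        return out

    # -- nonlinearities -------------------------------------------------------
    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * (1.0 - y * y))
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        out = Tensor(y, self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * y * (1.0 - y))
        return out

    def gelu(self):
        x = self.data
        phi = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        out = Tensor(x * phi, self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
                self._accum(g * (phi + x * pdf))

        out._backward = bw
        return out

    def log(self, eps: float = 1e-12):
        out = Tensor(np.log(self.data + eps), self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g / (self.data + eps))
        return out

    def softmax(self):
        """Row-wise softmax over the last axis."""
        z = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=-1, keepdims=True)
        out = Tensor(y, self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(y * (g - (g * y).sum(axis=-1, keepdims=True)))

        out._backward = bw
        return out

    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5):
        """Normalization over the last axis with learnable gain/offset."""
        mu = self.data.mean(axis=-1, keepdims=True)
        var = self.data.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (self.data - mu) * inv
        out = Tensor(gamma.data * xhat + beta.data,
                     self._needs(gamma, beta), (self, gamma, beta))

        def bw(g):
            if gamma.requires_grad:
                axes = tuple(range(g.ndim - 1))
                gamma._accum((g * xhat).sum(axis=axes))
            if beta.requires_grad:
                axes = tuple(range(g.ndim - 1))
                beta._accum(g.sum(axis=axes))
            if self.requires_grad:
                gx = g * gamma.data
                m1 = gx.mean(axis=-1, keepdims=True)
                m2 = (gx * xhat).mean(axis=-1, keepdims=True)
                self._accum((gx - m1 - xhat * m2) * inv)

        out._backward = bw
        return out

    def dropout(self, mask: np.ndarray):
        """Apply a precomputed inverted-dropout mask (already scaled by 1/(1-p))."""
        out = Tensor(self.data * mask, self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * mask)
        return out

    @staticmethod
    def stack(tensors, axis: int = 1) -> "Tensor":
        data = np.stack([t.data for t in tensors], axis=axis)
        needs = any(t.requires_grad for t in tensors)
        out = Tensor(data, needs, tuple(tensors))

        def bw(g):
            for i, t in enumerate(tensors):
                if t.requires_grad:
                    t._accum(np.take(g, i, axis=axis))

        out._backward = bw
        return out

    def gather_last(self, index: np.ndarray):
        """Pick index[...] along the last axis; used by the classification loss."""
        idx = np.expand_dims(index, -1)
        out = Tensor(np.take_along_axis(self.data, idx, -1).squeeze(-1),
                     self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.put_along_axis(full, idx, np.expand_dims(g, -1), -1)
                self._accum(full)

        out._backward = bw
        return out


def dropout_mask(rng: np.random.Generator, shape, p: float) -> np.ndarray:
    """Inverted-dropout mask: zeros with probability p, else 1/(1-p)."""
    if p <= 0.0:
        return np.ones(shape)
    return (rng.random(shape) >= p) / (1.0 - p)


class Adam:
    """Adam optimizer with the standard bias-corrected moment estimates."""

    def __init__(self, params: dict, lr: float = 3e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None
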