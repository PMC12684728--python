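"""Minimal reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine: each op builds a :class:`Tensor` holding the forward
value and a closure that routes the upstream gradient to its parents.  Only the
operations the encoders and losses need are provided; everything runs in
float64 for clean equivariance checks and reproducibility on CPU.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "scatter_add", "dropout"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad = None
        self._parents = _parents
        self._backward = _backward

    # ---- infrastructure -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

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

    # ---- arithmetic -----------------------------------------------------
    def _binary(self, other, fwd, bwd_a, bwd_b):
        other = other if isinstance(other, Tensor) else Tensor(other)
        rq = self.requires_grad or other.requires_grad
        out_data = fwd(self.data, other.data)

        def _bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(bwd_a(g, self.data, other.data), self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(bwd_b(g, self.data, other.data), other.data.shape)

        return Tensor(out_data, rq, (self, other), _bw if rq else None)

    def __add__(self, o):
        return self._binary(o, lambda a, b: a + b, lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __sub__(self, o):
        return self._binary(o, lambda a, b: a - b, lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, o):
        return Tensor(o).__sub__(self)

    def __mul__(self, o):
        return self._binary(o, lambda a, b: a * b, lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __truediv__(self, o):
        return self._binary(
            o, lambda a, b: a / b, lambda g, a, b: g / b, lambda g, a, b: -g * a / (b * b)
        )

    def __rtruediv__(self, o):
        return Tensor(o).__truediv__(self)

    def __neg__(self):
        return self * (-1.0)

    def __pow__(self, p: float):
        return self._unary(lambda a: a ** p, lambda g, a, y: g * p * a ** (p - 1))

    def __matmul__(self, o):
        return self._binary(
            o,
            lambda a, b: a @ b,
            lambda g, a, b: g @ np.swapaxes(b, -1, -2),
            lambda g, a, b: np.swapaxes(a, -1, -2) @ g,
        )

    # ---- elementwise ----------------------------------------------------
    def _unary(self, fwd, bwd):
        out_data = fwd(self.data)
        rq = self.requires_grad

        def _bw(g):
            self.grad += bwd(g, self.data, out_data)

        return Tensor(out_data, rq, (self,), _bw if rq else None)

    def exp(self):
        return self._unary(np.exp, lambda g, a, y: g * y)

    def log(self):
        return self._unary(np.log, lambda g, a, y: g / a)

    def sqrt(self):
        return self._unary(np.sqrt, lambda g, a, y: g * 0.5 / y)

    def tanh(self):
        return self._unary(np.tanh, lambda g, a, y: g * (1.0 - y * y))

    def relu(self):
        return self._unary(lambda a: np.maximum(a, 0.0), lambda g, a, y: g * (a > 0))

    def sigmoid(self):
        return self._unary(
            lambda a: 0.5 * (1.0 + np.tanh(0.5 * a)), lambda g, a, y: g * y * (1.0 - y)
        )

    # ---- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        rq = self.requires_grad

        def _bw(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self.grad += np.broadcast_to(gg, self.data.shape)

        return Tensor(out_data, rq, (self,), _bw if rq else None)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def _extreme(self, axis, argfn):
        idx = argfn(self.data, axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis).squeeze(axis)
        rq = self.requires_grad

        def _bw(g):
            buf = np.zeros_like(self.data)
            np.put_along_axis(buf, np.expand_dims(idx, axis), np.expand_dims(g, axis), axis=axis)
            self.grad += buf

        return Tensor(out_data, rq, (self,), _bw if rq else None)

    def max(self, axis: int):
        return self._extreme(axis, np.argmax)

    def min(self, axis: int):
        return self._extreme(axis, np.argmin)

    # ---- shape -----------------------------------------------------------
    def reshape(self, *shape):
        old = self.data.shape
        out_data = self.data.reshape(*shape)
        rq = self.requires_grad

        def _bw(g):
            self.grad += g.reshape(old)

        return Tensor(out_data, rq, (self,), _bw if rq else None)

    def swapaxes(self, a, b):
        out_data = np.swapaxes(self.data, a, b)
        rq = self.requires_grad

        def _bw(g):
            self.grad += np.swapaxes(g, a, b)

        return Tensor(out_data, rq, (self,), _bw if rq else None)

    def __getitem__(self, idx):
        out_data = self.data[idx]
        rq = self.requires_grad

        def _bw(g):
            np.add.at(self.grad, idx, g)

        return Tensor(out_data, rq, (self,), _bw if rq else None)

    # ---- composites -------------------------------------------------------
    def softmax(self, axis=-1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def log_softmax(self, axis=-1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()

    def norm(self, axis=-1, keepdims=False, eps: float = 1e-8):
        """Safe L2 norm along `axis` (gradient finite at 0)."""
        return ((self * self).sum(axis=axis, keepdims=keepdims) + eps).sqrt()


def concat(tensors, axis=0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    rq = any(t.requires_grad for t in tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t.grad += g[tuple(sl)]

    return Tensor(out_data, rq, tuple(tensors), _bw if rq else None)


def scatter_add(src: Tensor, index: np.ndarray, size: int) -> Tensor:
    """Sum rows of `src` into `size` bins along axis 0 (graph aggregation)."""
    index = np.asarray(index)
    out_data = np.zeros((size,) + src.data.shape[1:])
    np.add.at(out_data, index, src.data)
    rq = src.requires_grad

    def _bw(g):
        src.grad += g[index]

    return Tensor(out_data, rq, (src,), _bw if rq else None)


def dropout(x: Tensor, p: float, rng: np.random.Generator, active: bool) -> Tensor:
    if not active or p <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)
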