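"""Minimal reverse-mode automatic differentiation over numpy arrays.

Provides exactly the operations the survival transformer needs: broadcasted
arithmetic, (batched) matrix products, reshapes/transposes, slicing,
concatenation, reductions, layer normalization, row-wise softmax, GELU and
dropout, plus an Adam optimizer with L2 weight decay.  Gradients are checked
against central finite differences in the test suite.

All arrays are float64; graphs are built eagerly and freed after
:meth:`Tensor.backward`.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["Tensor", "Adam", "concat", "stack_rows"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _result(data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._result(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._result(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return self._result(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return self._result(self.data / other.data, (self, other), backward)

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 1:
                ga = g @ np.swapaxes(b, -1, -2) if b.ndim > 1 else g * b
            else:
                gb_t = np.swapaxes(b, -1, -2) if b.ndim > 1 else b[None, :]
                ga = g[..., None] @ gb_t if g.ndim == a.ndim - 1 else g @ gb_t
            if b.ndim == 1:
                gb = np.swapaxes(a, -1, -2) @ g if a.ndim > 1 else a * g
                gb = _unbroadcast(gb, b.shape) if gb.shape != b.shape else gb
            else:
                a_t = np.swapaxes(a, -1, -2) if a.ndim > 1 else a[:, None]
                g2 = g[..., None, :] if g.ndim == b.ndim - 1 else g
                gb = _unbroadcast(a_t @ g2, b.shape)
            return (_unbroadcast(ga, self.shape), gb)

        return self._result(self.data @ other.data, (self, other), backward)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        old = self.shape

        def backward(g):
            return (g.reshape(old),)

        return self._result(self.data.reshape(*shape), (self,), backward)

    def swapaxes(self, a, b):
        def backward(g):
            return (g.swapaxes(a, b),)

        return self._result(self.data.swapaxes(a, b), (self,), backward)

    def __getitem__(self, idx):
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return self._result(self.data[idx], (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if axis is None:
                return (np.full_like(self.data, 1.0) * g,)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, self.shape).copy(),)

        return self._result(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            return (g * out_data,)

        return self._result(out_data, (self,), backward)

    def log(self):
        def backward(g):
            return (g / self.data,)

        return self._result(np.log(self.data), (self,), backward)

    def gelu(self):
        """Exact (erf-based) Gaussian error linear unit."""
        from scipy.special import erf

        x = self.data
        cdf = 0.5 * (1.0 + erf(x / math.sqrt(2.0)))
        pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)

        def backward(g):
            return (g * (cdf + x * pdf),)

        return self._result(x * cdf, (self,), backward)

    def softmax(self, axis=-1):
        """Numerically stable softmax along ``axis``."""
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            return (s * (g - dot),)

        return self._result(s, (self,), backward)

    def layernorm(self, axis=-1, eps: float = 1e-5):
        """Normalize to zero mean / unit variance along ``axis`` (no affine)."""
        mu = self.data.mean(axis=axis, keepdims=True)
        xc = self.data - mu
        var = (xc * xc).mean(axis=axis, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        y = xc * inv
        n = self.data.shape[axis]

        def backward(g):
            gy = g
            gx = (inv / n) * (
                n * gy
                - gy.sum(axis=axis, keepdims=True)
                - y * (gy * y).sum(axis=axis, keepdims=True)
            )
            return (gx,)

        return self._result(y, (self,), backward)

    def dropout(self, rate: float, rng: np.random.Generator):
        """Inverted dropout; identity when ``rate`` is 0."""
        if rate <= 0.0:
            return self
        keep = 1.0 - rate
        mask = (rng.random(self.shape) < keep) / keep

        def backward(g):
            return (g * mask,)

        return self._result(self.data * mask, (self,), backward)

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can exceed the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64).reshape(self.shape)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad or g is None:
                    continue
                if parent.grad is None:
                    parent.grad = g.copy()
                else:
                    parent.grad += g
            node._backward = None
            node._parents = ()


def concat(tensors, axis=0):
    """Concatenate tensors along ``axis``."""
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._result(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )


def stack_rows(row: Tensor, n: int):
    """Tile a 1-D/2-D tensor as ``n`` leading copies (broadcast with gradient)."""
    data = np.broadcast_to(row.data, (n,) + row.data.shape).copy()

    def backward(g):
        return (g.sum(axis=0),)

    return Tensor._result(data, (row,), backward)


class Adam:
    """Adam with L2 weight decay (decay added to the gradient)."""

    def __init__(self, params: list[Tensor], lr: float = 0.002,
                 weight_decay: float = 0.0, betas=(0.9, 0.999), eps: float = 1e-8,
                 decay_mask: list[bool] | None = None):
        self.params = list(params)
        self.lr = lr
        self.weight_decay = weight_decay
        # by convention only weight matrices are decayed, not norm gains/biases
        self.decay_mask = (list(decay_mask) if decay_mask is not None
                           else [p.data.ndim >= 2 for p in self.params])
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data if self.decay_mask[i] else p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
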