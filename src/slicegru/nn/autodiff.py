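"""Minimal reverse-mode automatic differentiation on numpy arrays.

The trainable parts of the package (2D convolutional networks, the gated
recurrent cells, the dense heads) are expressed as compositions of the small
op set below.  Every op stores a closure computing vector-Jacobian products;
``Tensor.backward`` runs a topological sweep and accumulates gradients into
``Tensor.grad``.  All arithmetic is float64 so that the recurrent forward
pass can be compared against scalar-loop oracles at tight tolerances.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "max_pool2",
    "softmax_cross_entropy",
]


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")
    __array_priority__ = 100  # keep numpy from hijacking ``ndarray op Tensor``

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            stack = [(t, iter(t._parents))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen and p.requires_grad:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        return _add(self, _wrap(other))

    __radd__ = __add__

    def __mul__(self, other):
        return _mul(self, _wrap(other))

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_wrap(other))

    def __rsub__(self, other):
        return _wrap(other) + (-self)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise TypeError("division by a Tensor is not supported")
        return self * (1.0 / float(other))

    def __matmul__(self, other):
        return _matmul(self, _wrap(other))

    def __getitem__(self, key):
        return _getitem(self, key)

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        return _reshape(self, shape if len(shape) > 1 else shape[0])

    def sum(self, axis=None, keepdims=False):
        return _sum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis, keepdims) * (1.0 / n)

    # -- pointwise nonlinearities ----------------------------------------
    def sigmoid(self):
        out_data = _sigmoid(self.data)

        def bw(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return _make(out_data, (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            self._accumulate(g * (1.0 - out_data * out_data))

        return _make(out_data, (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._accumulate(g * mask)

        return _make(self.data * mask, (self,), bw)


def _sigmoid(x):
    # numerically stable logistic
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out


def _unbroadcast(g, shape):
    """Sum a gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def _add(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(a.data + b.data, (a, b), bw)


def _mul(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(a.data * b.data, (a, b), bw)


def _matmul(a: Tensor, b: Tensor) -> Tensor:
    if a.data.ndim != 2 or b.data.ndim != 2:
        raise ValueError("matmul supports 2-D operands only")

    def bw(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    return _make(a.data @ b.data, (a, b), bw)


def _reshape(a: Tensor, shape) -> Tensor:
    def bw(g):
        a._accumulate(g.reshape(a.data.shape))

    return _make(a.data.reshape(shape), (a,), bw)


def _getitem(a: Tensor, key) -> Tensor:
    def bw(g):
        full = np.zeros_like(a.data)
        full[key] = g
        a._accumulate(full)

    return _make(a.data[key], (a,), bw)


def _sum(a: Tensor, axis, keepdims) -> Tensor:
    def bw(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.data.shape).astype(np.float64))

    return _make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)


def concat(tensors, axis: int = -1) -> Tensor:
    """Concatenate tensors along ``axis`` (differentiable)."""
    tensors = [_wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1) -> Tensor:
    """Valid (no padding) 2-D convolution: (N,C,H,W) * (F,C,k,k) -> (N,F,Ho,Wo)."""
    n, c, h, wd = x.data.shape
    f, c2, k, k2 = w.data.shape
    if c != c2 or k != k2:
        raise ValueError("kernel shape inconsistent with input")
    ho = (h - k) // stride + 1
    wo = (wd - k) // stride + 1
    if ho <= 0 or wo <= 0:
        raise ValueError(f"kernel {k}x{k} too large for input {h}x{wd}")
    win = sliding_window_view(x.data, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    # (N, C, Ho, Wo, k, k) -> columns (N, C*k*k, Ho*Wo)
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, ho * wo)
    w2 = w.data.reshape(f, c * k * k)
    out = np.matmul(w2[None], cols).reshape(n, f, ho, wo)
    if b is not None:
        out = out + b.data.reshape(1, f, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        g2 = g.reshape(n, f, ho * wo)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            dw = np.einsum("nfp,ncp->fc", g2, cols)
            w._accumulate(dw.reshape(f, c, k, k))
        if x.requires_grad:
            dcols = np.matmul(w2.T[None], g2)  # (N, C*k*k, P)
            patch = dcols.reshape(n, c, k, k, ho, wo)
            dx = np.zeros_like(x.data)
            for ki in range(k):
                for kj in range(k):
                    dx[:, :, ki : ki + stride * ho : stride, kj : kj + stride * wo : stride] += patch[:, :, ki, kj]
            x._accumulate(dx)

    return _make(out, parents, bw)


def max_pool2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; a trailing odd row/column is dropped."""
    n, c, h, w = x.data.shape
    ho, wo = h // 2, w // 2
    blocks = (
        x.data[:, :, : 2 * ho, : 2 * wo]
        .reshape(n, c, ho, 2, wo, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, ho, wo, 4)
    )
    arg = blocks.argmax(axis=-1)
    out = np.take_along_axis(blocks, arg[..., None], axis=-1)[..., 0]

    def bw(g):
        g4 = np.zeros((n, c, ho, wo, 4))
        np.put_along_axis(g4, arg[..., None], g[..., None], axis=-1)
        dx = np.zeros_like(x.data)
        dx[:, :, : 2 * ho, : 2 * wo] = (
            g4.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, 2 * ho, 2 * wo)
        )
        x._accumulate(dx)

    return _make(out, (x,), bw)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer ``labels`` under softmax(logits)."""
    labels = np.asarray(labels, dtype=np.intp)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.data.shape[0]
    eps_logp = z[np.arange(n), labels] - np.log(ez.sum(axis=1))
    loss = -eps_logp.mean()

    def bw(g):
        d = probs.copy()
        d[np.arange(n), labels] -= 1.0
        logits._accumulate(g * d / n)

    return _make(np.float64(loss), (logits,), bw)
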