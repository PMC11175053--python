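"""Minimal reverse-mode automatic differentiation over numpy arrays.

The training loop needs gradients of composed scalar losses (cross entropy,
consistency, squared-distance terms) with respect to the parameters of two
small convolutional networks.  This module provides a compact tape-based
``Tensor`` supporting exactly the operations those networks use.  All math is
float64 numpy, so runs are bit-reproducible on a given platform.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "log_softmax", "softmax", "conv1d", "relu"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple = ()

    # -- graph construction helpers ---------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            a._accum(-g)

        return Tensor._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise TypeError("division only supported by scalars")
        return self * (1.0 / other)

    def __matmul__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(g @ np.swapaxes(b.data, -1, -2))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.data.shape))

        return Tensor._make(a.data @ b.data, (a, b), backward)

    def __pow__(self, p: float):
        a = self

        def backward(g):
            a._accum(g * p * a.data ** (p - 1))

        return Tensor._make(a.data**p, (a,), backward)

    # -- reductions / shaping ----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self

        def backward(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(gg, a.data.shape).copy())

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward(g):
            a._accum(g.reshape(a.data.shape))

        return Tensor._make(a.data.reshape(shape), (a,), backward)

    def transpose(self, axes):
        a = self
        inv = np.argsort(axes)

        def backward(g):
            a._accum(g.transpose(inv))

        return Tensor._make(a.data.transpose(axes), (a,), backward)

    def take_rows(self, index: np.ndarray):
        """Select ``out[i] = self[i, index[i]]`` along the last axis."""
        a = self
        index = np.asarray(index)
        rows = np.arange(self.data.shape[0])

        def backward(g):
            gg = np.zeros_like(a.data)
            np.add.at(gg, (rows, index), g)
            a._accum(gg)

        return Tensor._make(a.data[rows, index], (a,), backward)

    # -- backward pass -----------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("grad must be supplied for non-scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        x._accum(g * mask)

    return Tensor._make(x.data * mask, (x,), backward)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    z = x.data - m
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out_data = z - lse
    sm = np.exp(out_data)

    def backward(g):
        x._accum(g - sm * g.sum(axis=axis, keepdims=True))

    return Tensor._make(out_data, (x,), backward)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Plain numpy softmax (no gradient), numerically stable."""
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _unfold(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(B, T, C) -> (B, To, k, C) sliding windows over the time axis."""
    b, t, c = x.shape
    to = (t - k) // stride + 1
    s0, s1, s2 = x.strides
    return np.lib.stride_tricks.as_strided(
        x, shape=(b, to, k, c), strides=(s0, s1 * stride, s1, s2), writeable=False
    )


def conv1d(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 1, padding: int = 0) -> Tensor:
    """Temporal convolution. x: (B,T,Cin); weight: (K,Cin,Cout); bias: (Cout)."""
    k, cin, cout = weight.data.shape
    xd = x.data
    if padding:
        xd = np.pad(xd, ((0, 0), (padding, padding), (0, 0)))
    cols = _unfold(xd, k, stride)  # (B, To, K, Cin)
    b_, to = cols.shape[0], cols.shape[1]
    cols2 = cols.reshape(b_, to, k * cin)
    out_data = cols2 @ weight.data.reshape(k * cin, cout) + bias.data

    def backward(g):  # g: (B, To, Cout)
        if bias.requires_grad:
            bias._accum(g.sum(axis=(0, 1)))
        if weight.requires_grad:
            gw = cols2.reshape(-1, k * cin).T @ g.reshape(-1, cout)
            weight._accum(gw.reshape(k, cin, cout))
        if x.requires_grad:
            gcols = (g @ weight.data.reshape(k * cin, cout).T).reshape(b_, to, k, cin)
            gx = np.zeros_like(xd)
            for j in range(k):  # scatter-add each kernel offset
                idx = j + stride * np.arange(to)
                np.add.at(gx, (slice(None), idx), gcols[:, :, j])
            if padding:
                gx = gx[:, padding:-padding]
            x._accum(gx)

    return Tensor._make(out_data, (x, weight, bias), backward)
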