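"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operator set a small convolutional
super-resolution network needs: broadcasting arithmetic, ReLU/sigmoid,
axis reductions, reshape/transpose, 2-D cross-correlation (``conv2d``)
and the sub-pixel shuffle. Gradients are accumulated by a topological
backward sweep over the recorded tape.

Arrays are float64 throughout; convolutions use the NCHW layout.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "conv2d", "pixel_shuffle"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _result(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad += g

    # -- arithmetic -----------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._lift(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._result(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor._result(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._result(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor._result(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def square(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(2.0 * self.data * g)

        return Tensor._result(self.data**2, (self,), backward)

    def abs(self):
        # subgradient 0 at the kink
        def backward(g):
            if self.requires_grad:
                self._accumulate(np.sign(self.data) * g)

        return Tensor._result(np.abs(self.data), (self,), backward)

    # -- nonlinearities --------------------------------------------------------

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor._result(self.data * mask, (self,), backward)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s))

        return Tensor._result(s, (self,), backward)

    # -- reductions and views ---------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.full_like(self.data, g))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor._result(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old))

        return Tensor._result(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        return Tensor._result(self.data.transpose(axes), (self,), backward)

    # -- backprop ----------------------------------------------------------------

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def item(self) -> float:
        return float(self.data)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           padding: int = 0) -> Tensor:
    """2-D cross-correlation on NCHW input, stride 1, zero padding.

    weight is (out_channels, in_channels, kh, kw).
    """
    n, c, h, w = x.data.shape
    oc, ic, kh, kw = weight.data.shape
    if ic != c:
        raise ValueError(f"channel mismatch: input has {c}, weight expects {ic}")
    xp = x.data
    if padding:
        xp = np.pad(xp, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    ho = xp.shape[2] - kh + 1
    wo = xp.shape[3] - kw + 1
    if ho <= 0 or wo <= 0:
        raise ValueError("kernel larger than (padded) input")
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # n,c,ho,wo,kh,kw
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * ho * wo, c * kh * kw
    )
    wmat = weight.data.reshape(oc, -1)
    out = cols @ wmat.T
    if bias is not None:
        out += bias.data
    out_data = out.reshape(n, ho, wo, oc).transpose(0, 3, 1, 2)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        g2 = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, oc)
        if weight.requires_grad:
            weight._accumulate((g2.T @ cols).reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            # dx is the full correlation of g with the flipped kernel:
            # pad g by (k-1-padding) and run a second im2col matmul.
            ph, pw = kh - 1 - padding, kw - 1 - padding
            gp = np.pad(g, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
            gw = sliding_window_view(gp, (kh, kw), axis=(2, 3))
            gcols = gw.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, oc * kh * kw)
            wrot = weight.data[:, :, ::-1, ::-1].transpose(0, 2, 3, 1).reshape(
                oc * kh * kw, c
            )
            dx = (gcols @ wrot).reshape(n, h, w, c).transpose(0, 3, 1, 2)
            x._accumulate(dx)

    return Tensor._result(out_data, parents, backward)


def pixel_shuffle(x: Tensor, factor: int) -> Tensor:
    """Rearrange (N, C·r², H, W) into (N, C, rH, rW).

    out[n, c, r·h+dy, r·w+dx] = in[n, c·r² + dy·r + dx, h, w].
    """
    r = int(factor)
    n, crr, h, w = x.data.shape
    if crr % (r * r) != 0:
        raise ValueError(f"channel count {crr} not divisible by {r}^2")
    c = crr // (r * r)
    out_data = (
        x.data.reshape(n, c, r, r, h, w)
        .transpose(0, 1, 4, 2, 5, 3)
        .reshape(n, c, h * r, w * r)
    )

    def backward(g):
        if x.requires_grad:
            x._accumulate(
                g.reshape(n, c, h, r, w, r)
                .transpose(0, 1, 3, 5, 2, 4)
                .reshape(n, crr, h, w)
            )

    return Tensor._result(out_data, (x,), backward)
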