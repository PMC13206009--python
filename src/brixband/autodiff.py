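"""Reverse-mode automatic differentiation on numpy arrays.

This is the numerical core of the package: every trainable component
(attention, differentiable band gating, reconstruction, regression) is
expressed in these primitives so that the selection probabilities and the
soft pass-count receive exact gradients from both task losses.

The engine is deliberately small: float64 tensors, define-by-run graph,
topological-order backward pass. Every primitive's gradient is covered by
finite-difference tests.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "conv2d", "depthwise_conv2d", "conv1d",
           "avg_pool2d", "upsample_nearest2d", "pad2d", "sigmoid", "relu",
           "exp", "log", "sqrt"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple = ()
        self._backward = None

    # ---- graph construction helpers -------------------------------------

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    # ---- backward pass ---------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; training graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ---- arithmetic ------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def bw(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)
        out_data = self.data / other.data

        def bw(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                      other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("tensor exponent: use exp(p * log(x))")
        out_data = self.data ** exponent

        def bw(g):
            self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(out_data, (self,), bw)

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def bw(g):
            a, b = self.data, other.data
            a2 = a[None, :] if a.ndim == 1 else a
            b2 = b[:, None] if b.ndim == 1 else b
            g2 = g
            if a.ndim == 1:
                g2 = np.expand_dims(g2, -2)
            if b.ndim == 1:
                g2 = np.expand_dims(g2, -1)
            ga = g2 @ np.swapaxes(b2, -1, -2)
            gb = np.swapaxes(a2, -1, -2) @ g2
            self._accum(_unbroadcast(ga, a2.shape).reshape(a.shape))
            other._accum(_unbroadcast(gb, b2.shape).reshape(b.shape))

        return Tensor._make(out_data, (self, other), bw)

    # ---- reductions ------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy()
                            if np.ndim(g) else np.full_like(self.data, g))
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        # route gradient to the first argmax (deterministic tie-break)
        idx = self.data.argmax(axis=axis)

        def bw(g):
            gg = g if keepdims else np.expand_dims(g, axis)
            mask = np.zeros_like(self.data)
            np.put_along_axis(mask, np.expand_dims(idx, axis), 1.0, axis=axis)
            self._accum(mask * np.broadcast_to(gg, self.data.shape))

        return Tensor._make(out_data, (self,), bw)

    # ---- shape ops -------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        old = self.data.shape

        def bw(g):
            self._accum(g.reshape(old))

        return Tensor._make(out_data, (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g):
            self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), bw)

    def __getitem__(self, key):
        out_data = self.data[key]

        def bw(g):
            buf = np.zeros_like(self.data)
            np.add.at(buf, key, g)
            self._accum(buf)

        return Tensor._make(out_data, (self,), bw)


# ---- elementwise functions ----------------------------------------------

def exp(x: Tensor) -> Tensor:
    out_data = np.exp(x.data)

    def bw(g):
        x._accum(g * out_data)

    return Tensor._make(out_data, (x,), bw)


def log(x: Tensor) -> Tensor:
    def bw(g):
        x._accum(g / x.data)

    return Tensor._make(np.log(x.data), (x,), bw)


def sqrt(x: Tensor) -> Tensor:
    out_data = np.sqrt(x.data)

    def bw(g):
        x._accum(g * 0.5 / out_data)

    return Tensor._make(out_data, (x,), bw)


def sigmoid(x: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-np.clip(x.data, -500, 500)))

    def bw(g):
        x._accum(g * out_data * (1.0 - out_data))

    return Tensor._make(out_data, (x,), bw)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bw(g):
        x._accum(g * mask)

    return Tensor._make(x.data * mask, (x,), bw)


def concatenate(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), bw)


# ---- structured ops for (N, C, H, W) feature maps ------------------------

def pad2d(x: Tensor, pad: int) -> Tensor:
    """Zero-pad the two trailing spatial axes."""
    if pad == 0:
        return x
    widths = [(0, 0)] * (x.ndim - 2) + [(pad, pad), (pad, pad)]
    out_data = np.pad(x.data, widths)

    def bw(g):
        sl = (Ellipsis, slice(pad, -pad), slice(pad, -pad))
        x._accum(g[sl])

    return Tensor._make(out_data, (x,), bw)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           padding: int = 0) -> Tensor:
    """Stride-1 2-D cross-correlation.

    x: (N, Cin, H, W); w: (Cout, Cin, kh, kw); b: (Cout,).
    """
    xp = np.pad(x.data, [(0, 0), (0, 0), (padding, padding), (padding, padding)])
    n, cin, hp, wp = xp.shape
    cout, _, kh, kw = w.data.shape
    ho, wo = hp - kh + 1, wp - kw + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    # win: (N, Cin, Ho, Wo, kh, kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, cin * kh * kw)
    wmat = w.data.reshape(cout, -1)
    out = (cols @ wmat.T).reshape(n, ho, wo, cout).transpose(0, 3, 1, 2)
    if b is not None:
        out = out + b.data[None, :, None, None]

    def bw(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, cout)
        if w.requires_grad:
            w._accum((gmat.T @ cols).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = (gmat @ wmat).reshape(n, ho, wo, cin, kh, kw)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + ho, j:j + wo] += \
                        dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accum(dxp)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, bw)


def depthwise_conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     padding: int = 0) -> Tensor:
    """Per-channel stride-1 2-D cross-correlation.

    x: (N, C, H, W); w: (C, kh, kw); b: (C,).
    """
    xp = np.pad(x.data, [(0, 0), (0, 0), (padding, padding), (padding, padding)])
    n, c, hp, wp = xp.shape
    _, kh, kw = w.data.shape
    ho, wo = hp - kh + 1, wp - kw + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    out = np.einsum("nchwij,cij->nchw", win, w.data, optimize=True)
    if b is not None:
        out = out + b.data[None, :, None, None]

    def bw(g):
        if w.requires_grad:
            w._accum(np.einsum("nchwij,nchw->cij", win, g, optimize=True))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + ho, j:j + wo] += \
                        g * w.data[None, :, i, j, None, None]
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accum(dxp)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, bw)


def conv1d(x: Tensor, w: Tensor, padding: int = 0) -> Tensor:
    """Single-channel 1-D cross-correlation along the last axis.

    x: (N, L); w: (k,). Used for local cross-channel interaction.
    """
    xp = np.pad(x.data, [(0, 0), (padding, padding)])
    k = w.data.shape[0]
    lo = xp.shape[1] - k + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)  # (N, Lo, k)
    out = win @ w.data

    def bw(g):
        if w.requires_grad:
            w._accum(np.einsum("nlk,nl->k", win, g))
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for i in range(k):
                dxp[:, i:i + lo] += g * w.data[i]
            if padding:
                dxp = dxp[:, padding:-padding]
            x._accum(dxp)

    return Tensor._make(out, (x, w), bw)


def avg_pool2d(x: Tensor, factor: int = 2) -> Tensor:
    n, c, h, w = x.data.shape
    if h % factor or w % factor:
        raise ValueError("avg_pool2d requires divisible spatial dims")
    ho, wo = h // factor, w // factor
    out = x.data.reshape(n, c, ho, factor, wo, factor).mean(axis=(3, 5))

    def bw(g):
        gg = np.repeat(np.repeat(g, factor, axis=2), factor, axis=3)
        x._accum(gg / (factor * factor))

    return Tensor._make(out, (x,), bw)


def upsample_nearest2d(x: Tensor, factor: int = 2) -> Tensor:
    out = np.repeat(np.repeat(x.data, factor, axis=2), factor, axis=3)
    n, c, h, w = x.data.shape

    def bw(g):
        gg = g.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5))
        x._accum(gg)

    return Tensor._make(out, (x,), bw)
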