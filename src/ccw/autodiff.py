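"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine provides exactly the operator set the segmentation network needs:
broadcast arithmetic, matmul, stride-1 "same" convolution, 2x2 transposed
convolution, 2x2 max pooling, reductions with max/argmax, sigmoid/ReLU/exp/log,
reshape/transpose/concatenate.  Tensors record their parents and a backward
closure; :meth:`Tensor.backward` runs a topological sweep accumulating
gradients into ``.grad``.

All data is kept in float64.  The engine is deliberately small and eager —
there is no graph reuse, no in-place mutation of graph tensors, and no
device abstraction.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "_parents", "_backward", "name")

    def __init__(self, data, parents=(), name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)
        self._backward = None
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, name={self.name!r})"

    # ---- graph machinery -------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
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
        for node in topo:
            node.grad = None
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad = self.grad + grad

    # ---- elementwise arithmetic -----------------------------------------

    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    def __add__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data + other.data, (self, other))

        def back(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        out._backward = back
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data * other.data, (self, other))

        def back(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = back
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data / other.data, (self, other))

        def back(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(
                _unbroadcast(-g * self.data / other.data**2, other.data.shape)
            )

        out._backward = back
        return out

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, (self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    # ---- nonlinearities ---------------------------------------------------

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, (self,))
        out._backward = lambda g: self._accum(g * mask)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, (self,))
        out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, (self,))
        out._backward = lambda g: self._accum(g * e)
        return out

    def log(self):
        out = Tensor(np.log(self.data), (self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        return self**0.5

    # ---- reductions -------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        shape = self.data.shape

        def back(g):
            if axis is None:
                self._accum(np.broadcast_to(g, shape).copy())
                return
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            if not keepdims:
                g = np.expand_dims(g, tuple(a % len(shape) for a in axes))
            self._accum(np.broadcast_to(g, shape).copy())

        out._backward = back
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in ((axis,) if isinstance(axis, int) else axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        """Max along one axis; gradient flows to the (first) argmax."""
        idx = np.argmax(self.data, axis=axis)
        val = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis)
        out_data = val if keepdims else np.squeeze(val, axis=axis)
        out = Tensor(out_data, (self,))

        def back(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            full = np.zeros_like(self.data)
            np.put_along_axis(full, np.expand_dims(idx, axis), g, axis=axis)
            self._accum(full)

        out._backward = back
        return out

    # ---- shape ops ----------------------------------------------------------

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(*axes), (self,))
        out._backward = lambda g: self._accum(g.transpose(*inv))
        return out

    def __matmul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data @ other.data, (self, other))

        def back(g):
            self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.data.shape))
            other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.data.shape))

        out._backward = back
        return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out._backward = back
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Stride-1, same-padding 2-D convolution.

    ``x``: (N, C, H, W); ``w``: (O, C, kh, kw) with odd kh, kw; ``b``: (O,).
    """
    n, c, h, wd = x.data.shape
    o, c2, kh, kw = w.data.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input {c} vs kernel {c2}")
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("conv2d requires odd kernel sizes for same padding")
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    cols = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # N,C,H,W,kh,kw
    cols = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * h * wd, c * kh * kw
    )
    wmat = w.data.reshape(o, -1)
    out_data = (cols @ wmat.T).reshape(n, h, wd, o).transpose(0, 3, 1, 2)
    if b is not None:
        out_data = out_data + b.data.reshape(1, o, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, parents)

    def back(g):
        g2 = g.transpose(0, 2, 3, 1).reshape(n * h * wd, o)
        w._accum((g2.T @ cols).reshape(w.data.shape))
        if b is not None:
            b._accum(g.sum(axis=(0, 2, 3)))
        # input gradient = correlation of g with flipped, channel-swapped kernels
        wflip = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(c, -1)
        gp = np.pad(g, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        gcols = sliding_window_view(gp, (kh, kw), axis=(2, 3))
        gcols = np.ascontiguousarray(gcols.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * h * wd, o * kh * kw
        )
        x._accum((gcols @ wflip.T).reshape(n, h, wd, c).transpose(0, 3, 1, 2))

    out._backward = back
    return out


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """2x2-kernel, stride-2 transposed convolution (doubles H and W).

    ``x``: (N, C, H, W); ``w``: (C, O, 2, 2); ``b``: (O,).
    """
    n, c, h, wd = x.data.shape
    c2, o, kh, kw = w.data.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input {c} vs kernel {c2}")
    out6 = np.einsum("ncij,coab->noiajb", x.data, w.data)
    out_data = out6.reshape(n, o, h * kh, wd * kw)
    if b is not None:
        out_data = out_data + b.data.reshape(1, o, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, parents)

    def back(g):
        g6 = g.reshape(n, o, h, kh, wd, kw)
        w._accum(np.einsum("ncij,noiajb->coab", x.data, g6))
        if b is not None:
            b._accum(g.sum(axis=(0, 2, 3)))
        x._accum(np.einsum("noiajb,coab->ncij", g6, w.data))

    out._backward = back
    return out


def maxpool2d(x: Tensor) -> Tensor:
    """2x2, stride-2 max pooling; requires even H and W."""
    n, c, h, wd = x.data.shape
    if h % 2 or wd % 2:
        raise ValueError("maxpool2d requires even spatial dimensions")
    win = x.data.reshape(n, c, h // 2, 2, wd // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    win = win.reshape(n, c, h // 2, wd // 2, 4)
    idx = np.argmax(win, axis=-1)
    out = Tensor(np.take_along_axis(win, idx[..., None], axis=-1)[..., 0], (x,))

    def back(g):
        dwin = np.zeros((n, c, h // 2, wd // 2, 4))
        np.put_along_axis(dwin, idx[..., None], g[..., None], axis=-1)
        dx = dwin.reshape(n, c, h // 2, wd // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accum(dx.reshape(n, c, h, wd))

    out._backward = back
    return out


def softmax(x: Tensor, axis: int) -> Tensor:
    shift = np.max(x.data, axis=axis, keepdims=True)  # constant: does not change grads
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)
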