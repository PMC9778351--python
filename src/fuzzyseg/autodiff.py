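"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the compute core of the package: a small tape-based ``Tensor`` with
exactly the operators the segmentation networks need (dense convolution via
im2col, transposed convolution, pooling, pointwise math and reductions).
Gradients are accumulated by topological traversal of the recorded graph.

Layout convention is channels-first throughout: feature maps are
``(N, C, H, W)``.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "as_tensor", "concat", "log_softmax", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """An n-d array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64 if not isinstance(data, np.ndarray) else data.dtype)
        if self.data.dtype not in (np.float32, np.float64):
            self.data = self.data.astype(np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ utils
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    @staticmethod
    def _make(data: np.ndarray, parents: tuple["Tensor", ...],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad), self.data.shape)
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (defaults to d(self)/d(self) = 1)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        return Tensor._make(data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        return Tensor._make(data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g / other.data)
            if other.requires_grad:
                other._accum(-g * self.data / (other.data ** 2))

        return Tensor._make(data, (self, other), backward)

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) / self

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)
        data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g @ np.swapaxes(other.data, -1, -2))
            if other.requires_grad:
                other._accum(np.swapaxes(self.data, -1, -2) @ g)

        return Tensor._make(data, (self, other), backward)

    def pow(self, exponent: float) -> "Tensor":
        data = self.data ** exponent

        def backward(g):
            self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(data, (self,), backward)

    # -------------------------------------------------------------- pointwise
    def exp(self) -> "Tensor":
        data = np.exp(self.data)

        def backward(g):
            self._accum(g * data)

        return Tensor._make(data, (self,), backward)

    def log(self) -> "Tensor":
        data = np.log(self.data)

        def backward(g):
            self._accum(g / self.data)

        return Tensor._make(data, (self,), backward)

    def sqrt(self) -> "Tensor":
        return self.pow(0.5)

    def relu(self) -> "Tensor":
        mask = self.data > 0
        data = np.where(mask, self.data, 0.0)

        def backward(g):
            self._accum(g * mask)

        return Tensor._make(data, (self,), backward)

    def sigmoid(self) -> "Tensor":
        data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accum(g * data * (1.0 - data))

        return Tensor._make(data, (self,), backward)

    def clamp(self, lo: float | None = None, hi: float | None = None) -> "Tensor":
        data = np.clip(self.data, lo, hi)
        inside = np.ones_like(self.data, dtype=bool)
        if lo is not None:
            inside &= self.data >= lo
        if hi is not None:
            inside &= self.data <= hi

        def backward(g):
            self._accum(g * inside)

        return Tensor._make(data, (self,), backward)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        return Tensor._make(data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def max_detached(self, axis=None, keepdims: bool = False) -> "Tensor":
        """Max with the gradient stopped (used for stable softmax shifts)."""
        return Tensor(self.data.max(axis=axis, keepdims=keepdims))

    # ----------------------------------------------------------------- shapes
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        data = self.data.reshape(shape)

        def backward(g):
            self._accum(g.reshape(old))

        return Tensor._make(data, (self,), backward)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        data = self.data.transpose(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return Tensor._make(data, (self,), backward)

    def __getitem__(self, idx) -> "Tensor":
        data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor._make(data, (self,), backward)

    # ------------------------------------------------------------ convolution
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0) -> "Tensor":
        """2-D cross-correlation; ``weight`` is ``(Cout, Cin, k, k)``."""
        x, w = self.data, weight.data
        n, cin, h, wd = x.shape
        cout, cin_w, k, _ = w.shape
        if cin != cin_w:
            raise ValueError(f"conv2d channel mismatch: input has {cin}, kernel expects {cin_w}")
        s, p = stride, padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        ho = (h + 2 * p - k) // s + 1
        wo = (wd + 2 * p - k) // s + 1
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n, ho * wo, cin * k * k)
        wm = w.reshape(cout, -1)
        out = cols @ wm.T
        if bias is not None:
            out = out + bias.data
        out = out.transpose(0, 2, 1).reshape(n, cout, ho, wo)

        def backward(g):
            gl = g.reshape(n, cout, ho * wo).transpose(0, 2, 1)  # (N, L, Cout)
            if weight.requires_grad:
                gw = np.einsum("nlo,nlk->ok", gl, cols, optimize=True).reshape(w.shape)
                weight._accum(gw)
            if bias is not None and bias.requires_grad:
                bias._accum(gl.sum(axis=(0, 1)))
            if self.requires_grad:
                dcols = gl @ wm  # (N, L, Cin*k*k)
                d6 = dcols.reshape(n, ho, wo, cin, k, k).transpose(0, 3, 4, 5, 1, 2)
                gxp = np.zeros_like(xp)
                for i in range(k):
                    for j in range(k):
                        gxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += d6[:, :, i, j]
                self._accum(gxp[:, :, p:p + h, p:p + wd] if p else gxp)

        parents = (self, weight) if bias is None else (self, weight, bias)
        return Tensor._make(out, parents, backward)

    def conv_transpose2d(self, weight: "Tensor", bias: "Tensor | None" = None,
                         stride: int = 2) -> "Tensor":
        """Transposed convolution with kernel == stride (non-overlapping upsample).

        ``weight`` is ``(Cin, Cout, k, k)`` with ``k == stride``.
        """
        x, w = self.data, weight.data
        n, cin, h, wd = x.shape
        cin_w, cout, k, _ = w.shape
        if cin != cin_w:
            raise ValueError(f"conv_transpose2d channel mismatch: {cin} vs {cin_w}")
        if k != stride:
            raise ValueError("kernel size must equal stride for this operator")
        y6 = np.einsum("nchw,cokl->nohkwl", x, w, optimize=True)
        out = y6.reshape(n, cout, h * k, wd * k)
        if bias is not None:
            out = out + bias.data[None, :, None, None]

        def backward(g):
            g6 = g.reshape(n, cout, h, k, wd, k)
            if self.requires_grad:
                self._accum(np.einsum("nohkwl,cokl->nchw", g6, w, optimize=True))
            if weight.requires_grad:
                weight._accum(np.einsum("nchw,nohkwl->cokl", x, g6, optimize=True))
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))

        parents = (self, weight) if bias is None else (self, weight, bias)
        return Tensor._make(out, parents, backward)

    def maxpool2d(self, size: int = 2) -> "Tensor":
        x = self.data
        n, c, h, w = x.shape
        if h % size or w % size:
            raise ValueError(f"maxpool2d: spatial size {(h, w)} not divisible by {size}")
        ho, wo = h // size, w // size
        xr = x.reshape(n, c, ho, size, wo, size).transpose(0, 1, 2, 4, 3, 5)
        flat = np.ascontiguousarray(xr).reshape(n, c, ho, wo, size * size)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

        def backward(g):
            gflat = np.zeros_like(flat)
            np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
            gx = gflat.reshape(n, c, ho, wo, size, size).transpose(0, 1, 2, 4, 3, 5)
            self._accum(gx.reshape(n, c, h, w))

        return Tensor._make(out, (self,), backward)


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor._make(data, tuple(tensors), backward)


def log_softmax(x: Tensor, axis: int = 1) -> Tensor:
    """Numerically stable log-softmax along ``axis``."""
    z = x - x.max_detached(axis=axis, keepdims=True)
    return z - z.exp().sum(axis=axis, keepdims=True).log()


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    z = x - x.max_detached(axis=axis, keepdims=True)
    e = z.exp()
    return e / e.sum(axis=axis, keepdims=True)
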