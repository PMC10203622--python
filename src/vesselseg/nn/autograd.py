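"""Reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine sufficient for convolutional segmentation
networks: elementwise arithmetic with broadcasting, matmul, reductions,
2-D convolution with stride/dilation, bilinear 2x upsampling, and the
usual activations.  Gradients are accumulated into ``Tensor.grad`` by
``Tensor.backward()`` after a topological sort of the recorded graph.

The engine is deliberately minimal: single-threaded numpy, float32 by
default, no in-place op tracking, no higher-order gradients.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse

__all__ = [
    "Tensor",
    "as_tensor",
    "no_grad",
    "is_grad_enabled",
    "concat",
    "conv2d",
    "upsample_bilinear2x",
]

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Context manager disabling graph recording (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def is_grad_enabled() -> bool:
    return _grad_enabled


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and backprop closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _make(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- bookkeeping ----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        # free the tape
        for node in topo:
            if node is not self:
                node._backward = None
                node._parents = ()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- elementwise arithmetic ----------------------------------------------

    def __add__(self, other):
        other = as_tensor(other, like=self)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accumulate(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other, like=self))

    def __rsub__(self, other):
        return as_tensor(other, like=self) + (-self)

    def __mul__(self, other):
        other = as_tensor(other, like=self)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other, like=self)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other, like=self) / self

    def __pow__(self, exponent: float):
        exponent = float(exponent)

        def backward(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        return Tensor._make(self.data**exponent, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other, like=self)

        def backward(g):
            if self.requires_grad:
                self._accumulate(
                    _unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.data.shape)
                )
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.data.shape)
                )

        return Tensor._make(self.data @ other.data, (self, other), backward)

    # -- nonlinearities -------------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            self._accumulate(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accumulate(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def clip(self, low: float, high: float):
        """Clamp values; gradient is passed through on the interior only."""
        inside = (self.data > low) & (self.data < high)

        def backward(g):
            self._accumulate(g * inside)

        return Tensor._make(np.clip(self.data, low, high), (self,), backward)

    # -- reductions & shaping -------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        """Max along one axis; gradient flows to the first attaining entry."""
        out_data = self.data.max(axis=axis, keepdims=True)
        arg = self.data.argmax(axis=axis)

        def backward(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            full = np.zeros_like(self.data)
            np.put_along_axis(full, np.expand_dims(arg, axis), g, axis=axis)
            self._accumulate(full)

        return Tensor._make(
            out_data if keepdims else np.squeeze(out_data, axis), (self,), backward
        )

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old_shape = self.data.shape

        def backward(g):
            self._accumulate(g.reshape(old_shape))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def backward(g):
            self._accumulate(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)


def as_tensor(value, like: Tensor | None = None) -> Tensor:
    if isinstance(value, Tensor):
        return value
    dtype = like.data.dtype if like is not None else None
    return Tensor(np.asarray(value, dtype=dtype))


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
    dilation: int = 1,
) -> Tensor:
    """2-D cross-correlation of NCHW input with (F, C, kh, kw) kernels.

    Implemented as a loop over kernel taps, each tap a batched matmul over
    the correspondingly shifted input slice; the backward pass mirrors the
    same loop, so no im2col buffer is ever materialised.
    """
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    f, c_w, kh, kw = weight.data.shape
    if c_w != c:
        raise ValueError(f"kernel expects {c_w} input channels, got {c}")
    oh = (h + 2 * padding - dilation * (kh - 1) - 1) // stride + 1
    ow = (w + 2 * padding - dilation * (kw - 1) - 1) // stride + 1
    if oh <= 0 or ow <= 0:
        raise ValueError("convolution output would be empty")

    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    else:
        xp = x.data

    def tap(arr, ki, kj):
        return arr[
            :,
            :,
            ki * dilation : ki * dilation + (oh - 1) * stride + 1 : stride,
            kj * dilation : kj * dilation + (ow - 1) * stride + 1 : stride,
        ]

    wmat = weight.data  # (F, C, kh, kw)
    y = np.zeros((n, f, oh * ow), dtype=x.data.dtype)
    for ki in range(kh):
        for kj in range(kw):
            patch = np.ascontiguousarray(tap(xp, ki, kj)).reshape(n, c, -1)
            y += np.matmul(wmat[:, :, ki, kj], patch)
    y = y.reshape(n, f, oh, ow)
    if bias is not None:
        y = y + bias.data.reshape(1, f, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gf = g.reshape(n, f, -1)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        need_dx = x.requires_grad
        dxp = np.zeros_like(xp) if need_dx else None
        dw = np.zeros_like(weight.data) if weight.requires_grad else None
        for ki in range(kh):
            for kj in range(kw):
                if weight.requires_grad:
                    patch = np.ascontiguousarray(tap(xp, ki, kj)).reshape(n, c, -1)
                    dw[:, :, ki, kj] += np.einsum(
                        "nfl,ncl->fc", gf, patch, optimize=True
                    )
                if need_dx:
                    dpatch = np.matmul(wmat[:, :, ki, kj].T, gf)
                    tap(dxp, ki, kj)[...] += dpatch.reshape(n, c, oh, ow)
        if weight.requires_grad:
            weight._accumulate(dw)
        if need_dx:
            if padding:
                x._accumulate(dxp[:, :, padding : padding + h, padding : padding + w])
            else:
                x._accumulate(dxp)

    return Tensor._make(y, parents, backward)


_upsample_cache: dict[tuple[int, int], sparse.csr_matrix] = {}


def _bilinear2x_matrix(h: int, w: int) -> sparse.csr_matrix:
    """Sparse (4hw, hw) operator for x2 bilinear upsampling (center-aligned)."""

    def axis_weights(size):
        src = (np.arange(2 * size) + 0.5) / 2.0 - 0.5
        i0f = np.floor(src)
        t = src - i0f
        i0 = np.clip(i0f, 0, size - 1).astype(int)
        i1 = np.clip(i0f + 1, 0, size - 1).astype(int)
        return i0, i1, t

    iv0, iv1, tv = axis_weights(h)
    ih0, ih1, th = axis_weights(w)
    rows, cols, vals = [], [], []
    out_idx = np.arange(4 * h * w).reshape(2 * h, 2 * w)
    for vi, vw in ((iv0, 1.0 - tv), (iv1, tv)):
        for hi, hw_ in ((ih0, 1.0 - th), (ih1, th)):
            rows.append(out_idx.ravel())
            cols.append((vi[:, None] * w + hi[None, :]).ravel())
            vals.append((vw[:, None] * hw_[None, :]).ravel())
    mat = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(4 * h * w, h * w),
    )
    mat.sum_duplicates()
    return mat


def upsample_bilinear2x(x: Tensor) -> Tensor:
    """Double the spatial resolution of an NCHW tensor by bilinear interpolation.

    Sample centers are aligned (the convention of ``skimage.transform.resize``
    and torch's ``align_corners=False``); edge samples clamp to the border.
    """
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    key = (h, w)
    if key not in _upsample_cache:
        _upsample_cache[key] = _bilinear2x_matrix(h, w)
    mat = _upsample_cache[key]
    flat = x.data.reshape(n * c, h * w)
    out = (mat @ flat.T).T.reshape(n, c, 2 * h, 2 * w).astype(x.data.dtype)

    def backward(g):
        gflat = g.reshape(n * c, 4 * h * w)
        dx = (mat.T @ gflat.T).T.reshape(n, c, h, w).astype(x.data.dtype)
        x._accumulate(dx)

    return Tensor._make(out, (x,), backward)
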