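"""Minimal reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine, just large enough to train the attention U-Net
in :mod:`plaqueseg.network` on a CPU: broadcastable arithmetic, matmul,
stride-1 (optionally dilated) 2-D convolution, 2x2 stride-2 transposed
convolution, 2x2 max pooling, reductions, concatenation and the pointwise
nonlinearities the model needs.  All tensors are float32, laid out NCHW.

Gradients flow through closures recorded on a topologically-sorted tape,
in the style popularised by micrograd, but vectorised: every node wraps a
whole ndarray, not a scalar.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "relu", "sigmoid", "clip", "conv2d",
           "conv_transpose2x2", "maxpool2x2", "edge_pad2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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
    """An ndarray plus the machinery to backpropagate into it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple["Tensor", ...] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward

    # -- graph bookkeeping -------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; the graph can be deep
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))
        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))
        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))
        out._backward = bwd
        return out

    def exp(self):
        out = Tensor(np.exp(self.data), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * out.data)
        out._backward = bwd
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g / self.data)
        out._backward = bwd
        return out

    def matmul(self, other: "Tensor"):
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)
        out._backward = bwd
        return out

    # -- reductions & reshaping -------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape))
        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        """Max along one axis; ties send gradient to every maximal entry."""
        val = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == val)
        mask = mask / mask.sum(axis=axis, keepdims=True)
        out = Tensor(val if keepdims else np.squeeze(val, axis), parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(g * mask)
        out._backward = bwd
        return out

    def reshape(self, *shape: int):
        out = Tensor(self.data.reshape(shape), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.shape))
        out._backward = bwd
        return out


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])
    out._backward = bwd
    return out


def relu(x: Tensor) -> Tensor:
    """f(x) = max(0, x), applied elementwise."""
    out = Tensor(np.maximum(x.data, 0.0), parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * (x.data > 0))
    out._backward = bwd
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60.0, 60.0)))
    out = Tensor(s, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * s * (1.0 - s))
    out._backward = bwd
    return out


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes only where the clamp is inactive."""
    out = Tensor(np.clip(x.data, lo, hi), parents=(x,))
    inside = (x.data >= lo) & (x.data <= hi)

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * inside)
    out._backward = bwd
    return out


# -- convolution ----------------------------------------------------------

def _im2col(x: np.ndarray, k: int, dilation: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N, C*k*k, OH*OW) column matrix for a stride-1 conv."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = h + 2 * pad - dilation * (k - 1)
    ow = w + 2 * pad - dilation * (k - 1)
    # windows over the padded array, sampled with the dilation step
    cols = np.empty((n, c, k, k, oh, ow), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            di, dj = i * dilation, j * dilation
            cols[:, :, i, j] = xp[:, :, di:di + oh, dj:dj + ow]
    return cols.reshape(n, c * k * k, oh * ow)


def _col2im(cols: np.ndarray, shape: tuple[int, ...], k: int,
            dilation: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add back into the image)."""
    n, c, h, w = shape
    oh = h + 2 * pad - dilation * (k - 1)
    ow = w + 2 * pad - dilation * (k - 1)
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    cols = cols.reshape(n, c, k, k, oh, ow)
    for i in range(k):
        for j in range(k):
            di, dj = i * dilation, j * dilation
            xp[:, :, di:di + oh, dj:dj + ow] += cols[:, :, i, j]
    return xp[:, :, pad:pad + h, pad:pad + w]


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           dilation: int = 1, pad: int | None = None) -> Tensor:
    """Stride-1 2-D convolution with optional dilation.

    ``weight`` has shape (C_out, C_in, k, k).  By default padding keeps
    the output spatial size equal to the input's (requires odd k); pass
    ``pad=0`` for a valid convolution on pre-padded input.
    """
    cout, cin, k, _ = weight.shape
    n, c, h, w = x.shape
    if c != cin:
        raise ValueError(f"conv2d: input has {c} channels, weight expects {cin}")
    if pad is None:
        pad = dilation * (k - 1) // 2
    oh = h + 2 * pad - dilation * (k - 1)
    ow = w + 2 * pad - dilation * (k - 1)
    cols = _im2col(x.data, k, dilation, pad)           # (N, C*k*k, OH*OW)
    wmat = weight.data.reshape(cout, cin * k * k)
    y = np.einsum("oc,ncp->nop", wmat, cols, optimize=True).reshape(n, cout, oh, ow)
    if bias is not None:
        y = y + bias.data.reshape(1, cout, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(y, parents=parents)

    def bwd(g):
        gmat = g.reshape(n, cout, oh * ow)
        if weight.requires_grad:
            gw = np.einsum("nop,ncp->oc", gmat, cols, optimize=True)
            weight._accumulate(gw.reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = np.einsum("oc,nop->ncp", wmat, gmat, optimize=True)
            x._accumulate(_col2im(gcols, x.shape, k, dilation, pad))
    out._backward = bwd
    return out


def conv_transpose2x2(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """2x2 transposed convolution with stride 2 (the U-Net 'deconvolution').

    ``weight`` has shape (C_in, C_out, 2, 2).  Kernel size equals stride, so
    output positions receive exactly one contribution each and the op is a
    per-offset linear map followed by spatial interleaving.
    """
    cin, cout, _, _ = weight.shape
    n, c, h, w = x.shape
    if c != cin:
        raise ValueError(f"conv_transpose2x2: {c} channels, weight expects {cin}")
    y = np.empty((n, cout, 2 * h, 2 * w), dtype=np.float32)
    for a in range(2):
        for b in range(2):
            y[:, :, a::2, b::2] = np.einsum(
                "nchw,co->nohw", x.data, weight.data[:, :, a, b], optimize=True)
    if bias is not None:
        y += bias.data.reshape(1, cout, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(y, parents=parents)

    def bwd(g):
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        for a in range(2):
            for b in range(2):
                gs = g[:, :, a::2, b::2]
                if weight.requires_grad:
                    weight.grad = weight.grad if weight.grad is not None else \
                        np.zeros_like(weight.data)
                    weight.grad[:, :, a, b] += np.einsum(
                        "nchw,nohw->co", x.data, gs, optimize=True)
                if x.requires_grad:
                    gx = np.einsum("nohw,co->nchw", gs, weight.data[:, :, a, b],
                                   optimize=True)
                    x._accumulate(gx)
    out._backward = bwd
    return out


def edge_pad2d(x: Tensor, p: int) -> Tensor:
    """Replicate-pad the two trailing (spatial) axes by ``p`` pixels."""
    n, c, h, w = x.shape
    out = Tensor(np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)),
                        mode="edge"), parents=(x,))
    # each padded position copies one source pixel; the adjoint scatters
    iy = np.clip(np.arange(-p, h + p), 0, h - 1)
    ix = np.clip(np.arange(-p, w + p), 0, w - 1)

    def bwd(g):
        if not x.requires_grad:
            return
        gx = np.zeros_like(x.data)
        np.add.at(gx, (slice(None), slice(None), iy[:, None], ix[None, :]), g)
        x._accumulate(gx)
    out._backward = bwd
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2; requires even spatial dims."""
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2x2 requires even spatial dimensions")
    win = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    y = win.max(axis=(3, 5))
    out = Tensor(y, parents=(x,))
    # route gradient to the first maximal entry of each window
    flat = win.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    arg = flat.argmax(axis=-1)

    def bwd(g):
        if not x.requires_grad:
            return
        gwin = np.zeros_like(flat)
        np.put_along_axis(gwin, arg[..., None], g[..., None], axis=-1)
        gx = gwin.reshape(n, c, h // 2, w // 2, 2, 2).transpose(
            0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        x._accumulate(gx)
    out._backward = bwd
    return out
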