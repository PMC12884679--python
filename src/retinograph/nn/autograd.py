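"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations needed by the segmentation and node
classification networks: broadcasting arithmetic, matmul, 2-D convolution
with dilation (im2col), 2x2 max pooling, 2x2/stride-2 transposed
convolution, batch normalisation, sparse-dense products, ReLU/sigmoid/
softmax and reductions.  All tensors are float32 unless stated otherwise.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Tensor",
    "conv2d",
    "conv_transpose2d_2x2",
    "max_pool2d_2x2",
    "batch_norm",
    "spmm",
    "relu",
    "sigmoid",
    "softmax_rows",
    "dropout",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` back down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        # topological order over the DAG
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad)
        out._parents = (self, other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad)
        out._parents = (self, other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    __radd__ = __add__
    __rmul__ = __mul__

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad)
        out._parents = (self, other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = backward
        return out

    __matmul__ = matmul

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), self.requires_grad)
        out._parents = (self,)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        out._backward = backward
        return out

    def sum(self) -> "Tensor":
        out = Tensor(self.data.sum(), self.requires_grad)
        out._parents = (self,)

        def backward(g):
            if self.requires_grad:
                self._accumulate(np.broadcast_to(g, self.data.shape))

        out._backward = backward
        return out

    def mean(self) -> "Tensor":
        return self.sum() * (1.0 / self.data.size)

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), self.requires_grad)
        out._parents = (self,)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = backward
        return out

    def clip(self, lo: float, hi: float) -> "Tensor":
        out = Tensor(np.clip(self.data, lo, hi), self.requires_grad)
        out._parents = (self,)
        mask = (self.data > lo) & (self.data < hi)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        out._backward = backward
        return out


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), x.requires_grad)
    out._parents = (x,)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * (x.data > 0))

    out._backward = backward
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, x.requires_grad)
    out._parents = (x,)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * s * (1.0 - s))

    out._backward = backward
    return out


def softmax_rows(x: Tensor) -> Tensor:
    """Row-wise softmax for an (n, k) tensor."""
    z = x.data - x.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=1, keepdims=True)
    out = Tensor(s, x.requires_grad)
    out._parents = (x,)

    def backward(g):
        if x.requires_grad:
            dot = (g * s).sum(axis=1, keepdims=True)
            x._accumulate(s * (g - dot))

    out._backward = backward
    return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; identity when rate == 0."""
    if rate <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= rate).astype(np.float32) / (1.0 - rate)
    return x * Tensor(keep)


# -- image ops -----------------------------------------------------------


def _im2col(x: np.ndarray, kh: int, kw: int, dilation: int, pad: int):
    """Return columns of shape (N, C*kh*kw, H*W) for a same-size conv."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    # windows over the padded image at the dilated taps
    view = np.lib.stride_tricks.sliding_window_view(
        xp, ((kh - 1) * dilation + 1, (kw - 1) * dilation + 1), axis=(2, 3)
    )  # (n, c, H, W, ke, ke)
    view = view[:, :, :, :, ::dilation, ::dilation]  # (n, c, H, W, kh, kw)
    cols = view.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * kh * kw, h * w)
    return np.ascontiguousarray(cols)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           dilation: int = 1) -> Tensor:
    """Same-padding 2-D cross-correlation, NCHW layout.

    y[i] = sum_k x[i + r*k] * w[k] per spatial dimension, with zero padding
    chosen so the output spatial size equals the input's.  ``dilation`` is
    the sampling stride r of the input taps; r=1 is a standard convolution.
    """
    if dilation < 1:
        raise ValueError(f"dilation rate must be >= 1, got {dilation}")
    n, cin, h, wd = x.data.shape
    cout, cin_w, kh, kw = w.data.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin}, kernel {cin_w}")
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("same-padding conv requires odd kernel size")
    pad = (kh - 1) * dilation // 2
    cols = _im2col(x.data, kh, kw, dilation, pad)           # (n, C*k*k, HW)
    wmat = w.data.reshape(cout, cin * kh * kw)
    y = np.einsum("ok,nkp->nop", wmat, cols, optimize=True)
    y = y.reshape(n, cout, h, wd)
    if b is not None:
        y = y + b.data.reshape(1, cout, 1, 1)
    req = x.requires_grad or w.requires_grad or (b is not None and b.requires_grad)
    out = Tensor(y, req)
    out._parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gm = g.reshape(n, cout, h * wd)
        if w.requires_grad:
            dw = np.einsum("nop,nkp->ok", gm, cols, optimize=True)
            w._accumulate(dw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            # dx = correlation of g with the spatially flipped, channel-
            # transposed kernel at the same dilation and padding.
            wflip = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
            gcols = _im2col(g, kh, kw, dilation, pad)
            wfm = np.ascontiguousarray(wflip.reshape(cin, cout * kh * kw))
            dx = np.einsum("ck,nkp->ncp", wfm, gcols, optimize=True)
            x._accumulate(dx.reshape(x.data.shape))

    out._backward = backward
    return out


def max_pool2d_2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"spatial dims must be even for 2x2 pooling, got {h}x{w}")
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    xr = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    out = Tensor(y, x.requires_grad)
    out._parents = (x,)

    def backward(g):
        if x.requires_grad:
            dxr = np.zeros_like(xr)
            np.put_along_axis(dxr, idx[..., None], g[..., None], axis=-1)
            dx = dxr.reshape(n, c, h // 2, w // 2, 2, 2)
            dx = dx.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
            x._accumulate(dx)

    out._backward = backward
    return out


def conv_transpose2d_2x2(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Transposed convolution with a 2x2 kernel and stride 2 (upsampling).

    Kernel layout (cin, cout, 2, 2).  Because kernel size equals the
    stride, output 2x2 blocks do not overlap.
    """
    n, cin, h, wd = x.data.shape
    cin_w, cout, kh, kw = w.data.shape
    if cin != cin_w or (kh, kw) != (2, 2):
        raise ValueError("expected kernel of shape (cin, cout, 2, 2)")
    y = np.einsum("ncij,couv->noiujv", x.data, w.data, optimize=True)
    y = y.reshape(n, cout, 2 * h, 2 * wd)
    if b is not None:
        y = y + b.data.reshape(1, cout, 1, 1)
    req = x.requires_grad or w.requires_grad or (b is not None and b.requires_grad)
    out = Tensor(y, req)
    out._parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gb = g.reshape(n, cout, h, 2, wd, 2).transpose(0, 1, 2, 4, 3, 5)
        if x.requires_grad:
            dx = np.einsum("noijuv,couv->ncij", gb, w.data, optimize=True)
            x._accumulate(dx)
        if w.requires_grad:
            dw = np.einsum("ncij,noijuv->couv", x.data, gb, optimize=True)
            w._accumulate(dw)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    out._backward = backward
    return out


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, *,
               training: bool, running: dict, momentum: float = 0.1,
               eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalisation over (N, H, W) for NCHW input.

    ``running`` holds 'mean' and 'var' arrays updated in training mode and
    used verbatim in eval mode.
    """
    n, c, h, w = x.data.shape
    axes = (0, 2, 3)
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running["mean"] = (1 - momentum) * running["mean"] + momentum * mu
        running["var"] = (1 - momentum) * running["var"] + momentum * var
    else:
        mu, var = running["mean"], running["var"]
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(1, c, 1, 1)) * inv.reshape(1, c, 1, 1)
    y = gamma.data.reshape(1, c, 1, 1) * xhat + beta.data.reshape(1, c, 1, 1)
    req = x.requires_grad or gamma.requires_grad or beta.requires_grad
    out = Tensor(y, req)
    out._parents = (x, gamma, beta)
    m = n * h * w

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=axes))
        if x.requires_grad:
            gs = g * gamma.data.reshape(1, c, 1, 1)
            if training:
                s1 = gs.sum(axis=axes, keepdims=True)
                s2 = (gs * xhat).sum(axis=axes, keepdims=True)
                dx = (gs - s1 / m - xhat * s2 / m) * inv.reshape(1, c, 1, 1)
            else:
                dx = gs * inv.reshape(1, c, 1, 1)
            x._accumulate(dx)

    out._backward = backward
    return out


def spmm(a: sp.spmatrix, h: Tensor) -> Tensor:
    """Sparse (n,n) @ dense (n,d); ``a`` is a constant symmetric matrix."""
    acsr = a.tocsr()
    out = Tensor(acsr @ h.data, h.requires_grad)
    out._parents = (h,)

    def backward(g):
        if h.requires_grad:
            h._accumulate(acsr.T @ g)

    out._backward = backward
    return out
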