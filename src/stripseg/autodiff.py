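"""Reverse-mode automatic differentiation over NumPy arrays.

A small, self-contained autograd engine: a :class:`Tensor` wraps an
``ndarray``, records the operations applied to it, and :meth:`Tensor.backward`
accumulates gradients by walking the recorded graph in reverse topological
order.  Only the operations the segmentation network needs are provided —
elementwise arithmetic with broadcasting, matmul, reductions, sigmoid/relu/log,
2-D convolution (with stride, padding and dilation), average pooling and
bilinear upsampling.

All arithmetic is float64: the models here are deliberately small, and double
precision keeps finite-difference gradient checks tight.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "sigmoid",
    "relu",
    "log",
    "clip",
    "concat",
    "conv2d",
    "avg_pool2d",
    "upsample_bilinear",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, inverting NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an attached gradient and operation history."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, name: str | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()
        self.name = name

    # ---- construction helpers -------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, grad={'set' if self.grad is not None else 'none'})"

    # ---- graph plumbing --------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate; `grad` defaults to 1 for scalar outputs."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
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
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # ---- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data)
        out._parents = (self, other)

        def bw(g):
            self._accumulate(_unbroadcast(g, self.shape))
            other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data)
        out._parents = (self,)
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data)
        out._parents = (self, other)

        def bw(g):
            self._accumulate(_unbroadcast(g * other.data, self.shape))
            other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data)
        out._parents = (self, other)

        def bw(g):
            self._accumulate(_unbroadcast(g / other.data, self.shape))
            other._accumulate(_unbroadcast(-g * self.data / other.data**2, other.shape))

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent)
        out._parents = (self,)
        out._backward = lambda g: self._accumulate(g * exponent * self.data ** (exponent - 1))
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data)
        out._parents = (self, other)

        def bw(g):
            a, b = self.data, other.data
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            self._accumulate(_unbroadcast(ga, self.shape))
            other._accumulate(_unbroadcast(gb, other.shape))

        out._backward = bw
        return out

    # ---- reductions / shape ---------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims))
        out._parents = (self,)

        def bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape))
        out._parents = (self,)
        out._backward = lambda g: self._accumulate(g.reshape(self.shape))
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(axes) if axes else self.data.T)
        out._parents = (self,)
        inv = np.argsort(axes) if axes else None
        out._backward = lambda g: self._accumulate(
            g.transpose(inv) if inv is not None else g.T
        )
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---- nonlinearities ------------------------------------------------------

def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s)
    out._parents = (x,)
    out._backward = lambda g: x._accumulate(g * s * (1.0 - s))
    return out


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = Tensor(np.maximum(x.data, 0.0))
    out._parents = (x,)
    out._backward = lambda g: x._accumulate(g * (x.data > 0))
    return out


def log(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = Tensor(np.log(x.data))
    out._parents = (x,)
    out._backward = lambda g: x._accumulate(g / x.data)
    return out


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp; gradient passes only through unclipped entries."""
    x = as_tensor(x)
    out = Tensor(np.clip(x.data, lo, hi))
    out._parents = (x,)
    mask = (x.data >= lo) & (x.data <= hi)
    out._backward = lambda g: x._accumulate(g * mask)
    return out


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    out._parents = tuple(tensors)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    out._backward = bw
    return out


# ---- convolution ---------------------------------------------------------

def _conv_indices(C, H, W, kh, kw, sh, sw, dh, dw, Hout, Wout):
    i0 = dh * np.repeat(np.arange(kh), kw)
    i0 = np.tile(i0, C)
    i1 = sh * np.repeat(np.arange(Hout), Wout)
    j0 = dw * np.tile(np.arange(kw), kh * C)
    j1 = sw * np.tile(np.arange(Wout), Hout)
    i = i0.reshape(-1, 1) + i1.reshape(1, -1)  # (C*kh*kw, L)
    j = j0.reshape(-1, 1) + j1.reshape(1, -1)
    k = np.repeat(np.arange(C), kh * kw).reshape(-1, 1)
    return k, i, j


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
    dilation: int = 1,
) -> Tensor:
    """2-D cross-correlation on NCHW input via im2col.

    ``weight`` has shape (C_out, C_in, kh, kw); output spatial size follows the
    usual ``(H + 2p - d*(k-1) - 1)//s + 1`` rule.
    """
    x, weight = as_tensor(x), as_tensor(weight)
    N, C, H, W = x.shape
    O, C2, kh, kw = weight.shape
    if C != C2:
        raise ValueError(f"channel mismatch: input {C}, weight expects {C2}")
    sh = sw = stride
    dh = dw = dilation
    ph, pw = (padding, padding) if isinstance(padding, int) else padding
    Hout = (H + 2 * ph - dh * (kh - 1) - 1) // sh + 1
    Wout = (W + 2 * pw - dw * (kw - 1) - 1) // sw + 1
    if Hout < 1 or Wout < 1:
        raise ValueError("input too small for kernel/stride/dilation")
    xp = (
        np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        if (ph or pw)
        else x.data
    )
    k, i, j = _conv_indices(C, H + 2 * ph, W + 2 * pw, kh, kw, sh, sw, dh, dw, Hout, Wout)
    cols = xp[:, k, i, j]  # (N, C*kh*kw, L)
    wmat = weight.data.reshape(O, -1)
    out_data = np.einsum("ok,nkl->nol", wmat, cols).reshape(N, O, Hout, Wout)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, O, 1, 1)
    out = Tensor(out_data)
    parents = [x, weight] + ([bias] if bias is not None else [])
    out._parents = tuple(parents)

    def bw(g):
        gflat = g.reshape(N, O, -1)  # (N, O, L)
        gw = np.einsum("nol,nkl->ok", gflat, cols).reshape(weight.shape)
        weight._accumulate(gw)
        if bias is not None:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        gcols = np.einsum("ok,nol->nkl", wmat, gflat)
        gx = np.zeros((N, C, H + 2 * ph, W + 2 * pw))
        np.add.at(gx, (slice(None), k, i, j), gcols)
        x._accumulate(gx[:, :, ph : ph + H, pw : pw + W] if (ph or pw) else gx)

    out._backward = bw
    return out


def avg_pool2d(x: Tensor, d: int) -> Tensor:
    """Non-overlapping d×d mean pooling; trailing partial windows dropped."""
    x = as_tensor(x)
    N, C, H, W = x.shape
    if d < 1 or d > min(H, W):
        raise ValueError(f"pool window {d} invalid for {H}x{W} input")
    H0, W0 = H // d, W // d
    crop = x.data[:, :, : H0 * d, : W0 * d]
    out = Tensor(crop.reshape(N, C, H0, d, W0, d).mean(axis=(3, 5)))
    out._parents = (x,)

    def bw(g):
        gx = np.zeros_like(x.data)
        gx[:, :, : H0 * d, : W0 * d] = np.repeat(
            np.repeat(g, d, axis=2), d, axis=3
        ) / (d * d)
        x._accumulate(gx)

    out._backward = bw
    return out


def _bilinear_weights(in_size: int, out_size: int):
    """Source indices and weights for align_corners=False bilinear resizing."""
    if out_size == 1:
        src = np.zeros(1)
    else:
        src = (np.arange(out_size) + 0.5) * in_size / out_size - 0.5
    src = np.clip(src, 0, in_size - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, in_size - 1)
    frac = src - lo
    return lo, hi, frac


def upsample_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinear resize of NCHW input to (out_h, out_w); differentiable."""
    x = as_tensor(x)
    N, C, H, W = x.shape
    if (H, W) == (out_h, out_w):
        return x * 1.0
    ylo, yhi, fy = _bilinear_weights(H, out_h)
    xlo, xhi, fx = _bilinear_weights(W, out_w)
    fy = fy.reshape(-1, 1)
    fx = fx.reshape(1, -1)
    d = x.data
    top = d[:, :, ylo][:, :, :, xlo] * (1 - fx) + d[:, :, ylo][:, :, :, xhi] * fx
    bot = d[:, :, yhi][:, :, :, xlo] * (1 - fx) + d[:, :, yhi][:, :, :, xhi] * fx
    out = Tensor(top * (1 - fy) + bot * fy)
    out._parents = (x,)

    def bw(g):
        gx = np.zeros_like(d)
        w00 = g * (1 - fy) * (1 - fx)
        w01 = g * (1 - fy) * fx
        w10 = g * fy * (1 - fx)
        w11 = g * fy * fx
        yy_lo = ylo.reshape(-1, 1)
        yy_hi = yhi.reshape(-1, 1)
        xx_lo = xlo.reshape(1, -1)
        xx_hi = xhi.reshape(1, -1)
        np.add.at(gx, (slice(None), slice(None), yy_lo, xx_lo), w00)
        np.add.at(gx, (slice(None), slice(None), yy_lo, xx_hi), w01)
        np.add.at(gx, (slice(None), slice(None), yy_hi, xx_lo), w10)
        np.add.at(gx, (slice(None), slice(None), yy_hi, xx_hi), w11)
        x._accumulate(gx)

    out._backward = bw
    return out
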