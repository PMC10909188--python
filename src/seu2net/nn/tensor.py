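"""Reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` together with an optional gradient
and a backward closure; calling :meth:`Tensor.backward` on a scalar loss
walks the recorded tape in reverse topological order.  Only the operations
the segmentation networks in this package need are provided: broadcasting
arithmetic, matmul, ReLU/sigmoid/softmax, clamped log, reductions,
channel concatenation, 2-D convolution with dilation, 2x2 ceil-mode max
pooling, bilinear resampling and batch normalization.

All ops preserve the dtype of their inputs (float32 for training speed,
float64 in gradient-check tests).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "as_tensor",
    "add",
    "mul",
    "matmul",
    "relu",
    "sigmoid",
    "softmax",
    "log_clamped",
    "tsum",
    "tmean",
    "concat",
    "conv2d",
    "maxpool2x2",
    "upsample_bilinear",
    "batchnorm2d",
    "onehot_gather",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast from ``shape``."""
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
    """An ndarray node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- basic protocol ----------------------------------------------------
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

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, dtype={self.dtype}, grad={self.requires_grad})"

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -as_tensor(other))

    def __rsub__(self, other):
        return add(as_tensor(other), -self)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise TypeError("tensor/tensor division is not supported; multiply by a reciprocal")
        return mul(self, 1.0 / float(other))

    def __matmul__(self, other):
        return matmul(self, other)

    # -- autodiff ----------------------------------------------------------
    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node (a scalar unless ``grad`` is given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient requires a scalar")
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
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


class Parameter(Tensor):
    """A trainable tensor (``requires_grad`` always on)."""

    __slots__ = ()

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


def as_tensor(x, dtype=None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x, dtype=dtype)
    if arr.dtype.kind in "iub":
        arr = arr.astype(np.float64)
    return Tensor(arr)


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = any(p.requires_grad for p in parents)
        out._parents = tuple(parents)
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# elementwise and linear algebra
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data + b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.shape))
        b._accumulate(_unbroadcast(g, b.shape))

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    if not isinstance(b, Tensor) and np.isscalar(b):
        a = as_tensor(a)
        s = float(b)
        return _make(a.data * s, (a,), lambda g: a._accumulate(g * s))
    a, b = as_tensor(a), as_tensor(b)
    data = a.data * b.data

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.shape))
        b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _make(data, (a, b), backward)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data @ b.data

    def backward(g):
        a._accumulate(g @ b.data.T)
        b._accumulate(a.data.T @ g)

    return _make(data, (a, b), backward)


def relu(x) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0
    return _make(np.where(mask, x.data, 0), (x,), lambda g: x._accumulate(g * mask))


def sigmoid(x) -> Tensor:
    x = as_tensor(x)
    # numerically stable logistic
    y = np.empty_like(x.data)
    pos = x.data >= 0
    y[pos] = 1.0 / (1.0 + np.exp(-x.data[pos]))
    ex = np.exp(x.data[~pos])
    y[~pos] = ex / (1.0 + ex)
    return _make(y, (x,), lambda g: x._accumulate(g * y * (1.0 - y)))


def softmax(x, axis: int = 1) -> Tensor:
    x = as_tensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        x._accumulate(y * (g - dot))

    return _make(y, (x,), backward)


def log_clamped(x, eps: float = 1e-12) -> Tensor:
    """log(max(x, eps)); the gradient is zero where the clamp is active."""
    x = as_tensor(x)
    clamped = np.maximum(x.data, eps)
    active = x.data >= eps

    def backward(g):
        x._accumulate(np.where(active, g / clamped, 0.0))

    return _make(np.log(clamped), (x,), backward)


def tsum(x, axis=None, keepdims: bool = False) -> Tensor:
    x = as_tensor(x)
    data = x.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            x._accumulate(np.broadcast_to(g, x.shape).copy())
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        x._accumulate(np.broadcast_to(g, x.shape).copy())

    return _make(data, (x,), backward)


def tmean(x, axis=None, keepdims: bool = False) -> Tensor:
    x = as_tensor(x)
    n = x.data.size if axis is None else np.prod(
        [x.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(x, axis=axis, keepdims=keepdims), 1.0 / float(n))


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accumulate(g[tuple(idx)])

    return _make(data, ts, backward)


def reshape(x, shape) -> Tensor:
    x = as_tensor(x)
    return _make(x.data.reshape(shape), (x,), lambda g: x._accumulate(g.reshape(x.shape)))


# ---------------------------------------------------------------------------
# spatial ops (NCHW)
# ---------------------------------------------------------------------------

def _im2col_view(xp: np.ndarray, k: int, dilation: int, H: int, W: int) -> np.ndarray:
    """Strided (N, C, H, W, k, k) view on the padded input (no copy)."""
    n, c = xp.shape[:2]
    sN, sC, sH, sW = xp.strides
    return np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, c, H, W, k, k),
        strides=(sN, sC, sH, sW, sH * dilation, sW * dilation),
        writeable=False,
    )


def conv2d(x, weight, bias=None, dilation: int = 1) -> Tensor:
    """'Same' 2-D convolution (stride 1), NCHW, weight (out, in, k, k).

    Padding is ``dilation * (k - 1) // 2`` so spatial size is preserved
    for odd kernels.
    """
    x, weight = as_tensor(x), as_tensor(weight)
    bias = as_tensor(bias) if bias is not None else None
    n, cin, H, W = x.shape
    cout, cin_w, k, k2 = weight.shape
    if cin != cin_w or k != k2:
        raise ValueError(f"conv2d: input has {cin} channels, weight expects {cin_w} (kernel {k}x{k2})")
    pad = dilation * (k - 1) // 2
    if pad:
        xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    else:
        xp = x.data
    if k == 1:
        out = np.tensordot(weight.data[:, :, 0, 0], xp, axes=([1], [1]))  # (cout, n, H, W)
        out = out.transpose(1, 0, 2, 3).copy()
    else:
        view = _im2col_view(xp, k, dilation, H, W)
        out = np.tensordot(view, weight.data, axes=([1, 4, 5], [1, 2, 3]))  # (n, H, W, cout)
        out = out.transpose(0, 3, 1, 2).copy()
    if bias is not None:
        out += bias.data[None, :, None, None]

    def backward(g):
        if bias is not None:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if k == 1:
            gw = np.tensordot(g, xp, axes=([0, 2, 3], [0, 2, 3]))[:, :, None, None]
            weight._accumulate(gw)
            gx = np.tensordot(weight.data[:, :, 0, 0].T, g, axes=([1], [1])).transpose(1, 0, 2, 3)
            x._accumulate(gx)
            return
        gw = np.empty_like(weight.data)
        gxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                sl = xp[:, :, i * dilation : i * dilation + H, j * dilation : j * dilation + W]
                gw[:, :, i, j] = np.tensordot(g, sl, axes=([0, 2, 3], [0, 2, 3]))
                gxp[:, :, i * dilation : i * dilation + H, j * dilation : j * dilation + W] += (
                    np.tensordot(weight.data[:, :, i, j].T, g, axes=([1], [1])).transpose(1, 0, 2, 3)
                )
        weight._accumulate(gw)
        x._accumulate(gxp[:, :, pad : pad + H, pad : pad + W] if pad else gxp)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _make(out, parents, backward)


def maxpool2x2(x) -> Tensor:
    """2x2 stride-2 max pooling with ceiling semantics (odd edges padded)."""
    x = as_tensor(x)
    n, c, H, W = x.shape
    Ho, Wo = (H + 1) // 2, (W + 1) // 2
    ph, pw = Ho * 2 - H, Wo * 2 - W
    xp = x.data
    if ph or pw:
        xp = np.pad(xp, ((0, 0), (0, 0), (0, ph), (0, pw)), constant_values=-np.inf)
    win = xp.reshape(n, c, Ho, 2, Wo, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, Ho, Wo, 4)
    idx = win.argmax(axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gwin = np.zeros((n, c, Ho, Wo, 4), dtype=g.dtype)
        np.put_along_axis(gwin, idx[..., None], g[..., None], axis=-1)
        gp = gwin.reshape(n, c, Ho, Wo, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, Ho * 2, Wo * 2)
        x._accumulate(gp[:, :, :H, :W])

    return _make(out, (x,), backward)


def _interp_matrix(n_in: int, n_out: int, dtype) -> np.ndarray:
    """Dense 1-D bilinear interpolation matrix (n_out x n_in), half-pixel centers."""
    m = np.zeros((n_out, n_in), dtype=np.float64)
    if n_in == 1:
        m[:, 0] = 1.0
        return m.astype(dtype)
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w1 = src - i0
    np.add.at(m, (np.arange(n_out), i0), 1.0 - w1)
    np.add.at(m, (np.arange(n_out), i1), w1)
    return m.astype(dtype)


def upsample_bilinear(x, size: tuple[int, int]) -> Tensor:
    """Bilinear resampling to ``size`` (half-pixel-center convention)."""
    x = as_tensor(x)
    n, c, H, W = x.shape
    Ho, Wo = size
    if (Ho, Wo) == (H, W):
        return _make(x.data.copy(), (x,), lambda g: x._accumulate(g))
    R = _interp_matrix(H, Ho, x.dtype)   # (Ho, H)
    C = _interp_matrix(W, Wo, x.dtype)   # (Wo, W)
    out = np.einsum("oh,nchw,pw->ncop", R, x.data, C, optimize=True)

    def backward(g):
        x._accumulate(np.einsum("oh,ncop,pw->nchw", R, g, C, optimize=True))

    return _make(out, (x,), backward)


def batchnorm2d(
    x,
    gamma,
    beta,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization over (N, H, W).

    In training mode the batch statistics normalize and the running
    buffers are updated in place (unbiased variance, like the common
    deep-learning convention); in evaluation mode the running buffers
    normalize and the op is a per-channel affine map.
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    n, c, H, W = x.shape
    if training:
        m = n * H * W
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * (var * (m / max(m - 1, 1)))
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x.data - mean[None, :, None, None]) * inv[None, :, None, None]
        out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

        def backward(g):
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
            beta._accumulate(g.sum(axis=(0, 2, 3)))
            gh = g * gamma.data[None, :, None, None]
            s1 = gh.sum(axis=(0, 2, 3), keepdims=True)
            s2 = (gh * xhat).sum(axis=(0, 2, 3), keepdims=True)
            x._accumulate(inv[None, :, None, None] * (gh - s1 / m - xhat * s2 / m))

        return _make(out, (x, gamma, beta), backward)

    inv = 1.0 / np.sqrt(running_var + eps)
    scale = (gamma.data * inv).astype(x.dtype)
    shift = (beta.data - gamma.data * running_mean * inv).astype(x.dtype)
    out = x.data * scale[None, :, None, None] + shift[None, :, None, None]
    xhat_ = (x.data - running_mean[None, :, None, None]) * inv[None, :, None, None]

    def backward_eval(g):
        gamma._accumulate((g * xhat_).sum(axis=(0, 2, 3)))
        beta._accumulate(g.sum(axis=(0, 2, 3)))
        x._accumulate(g * scale[None, :, None, None])

    return _make(out, (x, gamma, beta), backward_eval)


def onehot_gather(p, labels: np.ndarray) -> Tensor:
    """Per-pixel probability of the true class: (N,C,H,W), (N,H,W) -> (N,H,W)."""
    p = as_tensor(p)
    lab = labels[:, None, :, :]
    out = np.take_along_axis(p.data, lab, axis=1)[:, 0]

    def backward(g):
        gp = np.zeros_like(p.data)
        np.put_along_axis(gp, lab, g[:, None], axis=1)
        p._accumulate(gp)

    return _make(out, (p,), backward)
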