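"""Minimal reverse-mode automatic differentiation over numpy arrays.

Only the operations the reconstruction models and their loss need are
implemented: elementwise arithmetic with broadcasting, matmul, 2-D
convolution (stride 1, zero 'same' padding), softmax, ReLU/GELU, reshape /
transpose / concat, reductions, and a Gaussian blur restricted to fully
covered windows (the building block of the differentiable SSIM term).
Every op's vector-Jacobian product is exact and checked against finite
differences in the test suite.

Arrays are kept in float32; gradients accumulate into ``Tensor.grad``.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import correlate1d


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents: Tuple["Tensor", ...] = ()
        self._backward: Optional[Callable[[np.ndarray], None]] = None

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: List[Tensor] = []
        seen = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        return div(self, other)

    def __neg__(self):
        return mul(self, -1.0)

    def reshape(self, *shape):
        return reshape(self, shape)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: np.ndarray, parents: Sequence[Tensor],
          backward: Callable[[np.ndarray], None]) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum a gradient down to the broadcast-source shape."""
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# -- elementwise ----------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad or a._parents:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad or b._parents:
            b._accumulate(_unbroadcast(g, b.shape))

    return _node(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad or a._parents:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad or b._parents:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _node(out_data, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data / b.data

    def backward(g):
        if a.requires_grad or a._parents:
            a._accumulate(_unbroadcast(g / b.data, a.shape))
        if b.requires_grad or b._parents:
            b._accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

    return _node(out_data, (a, b), backward)


def absolute(a) -> Tensor:
    a = _wrap(a)
    out_data = np.abs(a.data)
    sign = np.sign(a.data)

    def backward(g):
        a._accumulate(g * sign)

    return _node(out_data, (a,), backward)


def relu(a) -> Tensor:
    a = _wrap(a)
    mask = a.data > 0

    def backward(g):
        a._accumulate(g * mask)

    return _node(a.data * mask, (a,), backward)


_GELU_C = np.float32(np.sqrt(2.0 / np.pi))


def gelu(a) -> Tensor:
    """GELU, tanh approximation (smooth, cheap, standard in transformer blocks)."""
    a = _wrap(a)
    x = a.data
    u = _GELU_C * (x + 0.044715 * x**3)
    t = np.tanh(u)
    out_data = 0.5 * x * (1.0 + t)

    def backward(g):
        du = _GELU_C * (1.0 + 3 * 0.044715 * x * x)
        grad = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * du
        a._accumulate(g * grad)

    return _node(out_data, (a,), backward)


def softmax(a, axis: int = -1) -> Tensor:
    a = _wrap(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        a._accumulate(y * (g - (g * y).sum(axis=axis, keepdims=True)))

    return _node(y, (a,), backward)


# -- shape ops -------------------------------------------------------------

def reshape(a, shape) -> Tensor:
    a = _wrap(a)
    old = a.shape

    def backward(g):
        a._accumulate(g.reshape(old))

    return _node(a.data.reshape(shape), (a,), backward)


def transpose(a, axes) -> Tensor:
    a = _wrap(a)
    inv = np.argsort(axes)

    def backward(g):
        a._accumulate(g.transpose(inv))

    return _node(a.data.transpose(axes), (a,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    ts = [_wrap(t) for t in tensors]
    sizes = [t.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    return _node(np.concatenate([t.data for t in ts], axis=axis), ts, backward)


# -- reductions ------------------------------------------------------------

def mean(a) -> Tensor:
    a = _wrap(a)
    n = a.data.size

    def backward(g):
        a._accumulate(np.broadcast_to(g / n, a.shape).astype(np.float32))

    return _node(a.data.mean(), (a,), backward)


def total(a) -> Tensor:
    a = _wrap(a)

    def backward(g):
        a._accumulate(np.broadcast_to(g, a.shape).astype(np.float32))

    return _node(a.data.sum(), (a,), backward)


# -- linear algebra --------------------------------------------------------

def matmul(a, b) -> Tensor:
    """Batched matrix product via numpy matmul semantics (no broadcasting of
    batch dims between the two operands beyond what matmul itself allows)."""
    a, b = _wrap(a), _wrap(b)
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad or a._parents:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.shape))
        if b.requires_grad or b._parents:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.shape))

    return _node(out_data, (a, b), backward)


# -- convolution -----------------------------------------------------------

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*k*k) patches under zero 'same' padding."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N, C, H, W, k, k)
    cols = win.transpose(0, 2, 3, 1, 4, 5)
    n, h, w = x.shape[0], x.shape[2], x.shape[3]
    return np.ascontiguousarray(cols).reshape(n * h * w, -1)


def _conv_forward(x: np.ndarray, w: np.ndarray, b: Optional[np.ndarray]):
    n, _, h, wd = x.shape
    o, c, k, _ = w.shape
    cols = _im2col(x, k)
    out = cols @ w.reshape(o, c * k * k).T
    if b is not None:
        out += b
    return out.reshape(n, h, wd, o).transpose(0, 3, 1, 2), cols


def conv2d(x, weight, bias=None) -> Tensor:
    """2-D convolution, stride 1, odd kernel, zero 'same' padding.

    x: (N, C, H, W); weight: (O, C, k, k); bias: (O,) or None.
    """
    x, weight = _wrap(x), _wrap(weight)
    bias_t = _wrap(bias) if bias is not None else None
    o, c, k, _ = weight.shape
    out_data, cols = _conv_forward(x.data, weight.data, None if bias_t is None else bias_t.data)
    n, _, h, wd = x.shape

    def backward(g):
        g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * h * wd, o)
        if weight.requires_grad or weight._parents:
            weight._accumulate((g2.T @ cols).reshape(o, c, k, k))
        if bias_t is not None and (bias_t.requires_grad or bias_t._parents):
            bias_t._accumulate(g2.sum(axis=0))
        if x.requires_grad or x._parents:
            # gradient w.r.t. input = convolution with the transposed,
            # spatially flipped kernel (exact for stride 1 / same padding)
            w_t = np.ascontiguousarray(weight.data.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1])
            gx, _ = _conv_forward(g, w_t, None)
            x._accumulate(gx)

    parents = (x, weight) if bias_t is None else (x, weight, bias_t)
    return _node(out_data, parents, backward)


# -- Gaussian blur on fully covered windows --------------------------------

def gaussian_kernel1d(sigma: float = 1.5, radius: int = 5) -> np.ndarray:
    xs = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-(xs**2) / (2.0 * sigma**2))
    return (k / k.sum()).astype(np.float32)


def _blur2d(x: np.ndarray, k1d: np.ndarray) -> np.ndarray:
    y = correlate1d(x, k1d, axis=-1, mode="constant", cval=0.0)
    return correlate1d(y, k1d, axis=-2, mode="constant", cval=0.0)


def blur_valid(a, sigma: float = 1.5, radius: int = 5) -> Tensor:
    """Separable Gaussian filter over the last two axes, cropped to windows
    fully inside the image (each side loses ``radius`` pixels).

    The zero-padded symmetric filter is self-adjoint, so the backward pass
    embeds the gradient in zeros and applies the same filter.
    """
    a = _wrap(a)
    if a.shape[-1] <= 2 * radius or a.shape[-2] <= 2 * radius:
        raise ValueError(f"image smaller than the {2 * radius + 1}x{2 * radius + 1} window")
    k1d = gaussian_kernel1d(sigma, radius)
    full = _blur2d(a.data, k1d)
    out_data = full[..., radius:-radius, radius:-radius].copy()

    def backward(g):
        gfull = np.zeros(a.shape, dtype=np.float32)
        gfull[..., radius:-radius, radius:-radius] = g
        a._accumulate(_blur2d(gfull, k1d))

    return _node(out_data, (a,), backward)
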