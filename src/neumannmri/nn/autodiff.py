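"""Minimal reverse-mode automatic differentiation on numpy arrays.

The unrolled reconstruction networks in this package interleave real-valued
convolutional blocks with complex linear operators (Fourier transforms,
sampling masks, coil-sensitivity products).  This module provides the small
set of differentiable primitives those models need, on plain numpy arrays.

Gradient convention for complex tensors: for a real-valued loss ``L`` and a
complex node ``z = x + iy`` the stored gradient is the conjugate Wirtinger
derivative ``dL/dx + i dL/dy``, so that for a C-linear map ``u = A z`` the
chain rule is ``grad_z = A^H grad_u``, and gradient descent steps
``z -= lr * grad`` decrease ``L``.  Real tensors reduce to ordinary calculus.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "astensor",
    "add", "mul", "div", "neg", "power",
    "tsum", "tmean", "reshape", "getitem", "concat", "pad2d", "crop2d",
    "matmul", "leaky_relu", "sqrt", "square",
    "conv2d", "avg_pool2", "upsample_nearest2", "uniform_filter_valid",
    "real", "imag", "make_complex", "conj", "cabs",
    "fft2c_t", "ifft2c_t",
    "pack_channels_t", "unpack_channels_t",
]


class Tensor:
    """A node in the computation graph wrapping a numpy array."""

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=()):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p, _ in parents
        )
        # parents: tuple of (Tensor, vjp) kept only while grads are needed
        self._parents = tuple(parents) if self.requires_grad else ()

    # -- graph -----------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient on non-scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p, _ in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad and not t._parents:  # leaf
                t.grad = g if t.grad is None else t.grad + g
            for p, vjp in t._parents:
                if not p.requires_grad:
                    continue
                pg = vjp(g)
                # a real node feeding a complex op receives Re of the cotangent
                if np.iscomplexobj(pg) and not np.iscomplexobj(p.data):
                    pg = pg.real
                k = id(p)
                grads[k] = pg if k not in grads else grads[k] + pg

    # -- conveniences ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def item(self):
        return self.data.item()

    def __add__(self, o):
        return add(self, o)

    __radd__ = __add__

    def __neg__(self):
        return neg(self)

    def __sub__(self, o):
        return add(self, neg(astensor(o)))

    def __rsub__(self, o):
        return add(astensor(o), neg(self))

    def __mul__(self, o):
        return mul(self, o)

    __rmul__ = __mul__

    def __truediv__(self, o):
        return div(self, o)

    def __rtruediv__(self, o):
        return div(astensor(o), self)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, grad={self.requires_grad})"


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    if g.shape == tuple(shape):
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise algebra
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    return Tensor(
        a.data + b.data,
        parents=(
            (a, lambda g: _unbroadcast(g, a.shape)),
            (b, lambda g: _unbroadcast(g, b.shape)),
        ),
    )


def neg(a) -> Tensor:
    a = astensor(a)
    return Tensor(-a.data, parents=((a, lambda g: -g),))


def mul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    ad, bd = a.data, b.data
    return Tensor(
        ad * bd,
        parents=(
            (a, lambda g: _unbroadcast(g * np.conj(bd), a.shape)),
            (b, lambda g: _unbroadcast(g * np.conj(ad), b.shape)),
        ),
    )


def div(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    ad, bd = a.data, b.data
    out = ad / bd
    return Tensor(
        out,
        parents=(
            (a, lambda g: _unbroadcast(g * np.conj(1.0 / bd), a.shape)),
            (b, lambda g: _unbroadcast(g * np.conj(-out / bd), b.shape)),
        ),
    )


def power(a, p: float) -> Tensor:
    """Elementwise real power with constant exponent (real tensors)."""
    a = astensor(a)
    ad = a.data
    out = ad ** p
    return Tensor(out, parents=((a, lambda g: g * p * ad ** (p - 1)),))


def sqrt(a) -> Tensor:
    a = astensor(a)
    out = np.sqrt(a.data)
    return Tensor(out, parents=((a, lambda g: g * (0.5 / out)),))


def square(a) -> Tensor:
    return mul(a, a)


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = astensor(a)
    scale = np.where(a.data >= 0, 1.0, slope)
    return Tensor(a.data * scale, parents=((a, lambda g: g * scale),))


# ---------------------------------------------------------------------------
# reductions and shape ops
# ---------------------------------------------------------------------------

def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = astensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        if axis is None:
            return np.broadcast_to(g, a.shape).copy()
        gg = g
        if not keepdims:
            gg = np.expand_dims(g, axis)
        return np.broadcast_to(gg, a.shape).copy()

    return Tensor(out, parents=((a, vjp),))


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = astensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def reshape(a, shape) -> Tensor:
    a = astensor(a)
    old = a.shape
    return Tensor(
        a.data.reshape(shape), parents=((a, lambda g: g.reshape(old)),)
    )


def getitem(a, idx) -> Tensor:
    a = astensor(a)

    def vjp(g):
        out = np.zeros(a.shape, dtype=g.dtype)
        np.add.at(out, idx, g)
        return out

    return Tensor(a.data[idx], parents=((a, vjp),))


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def make_vjp(i):
        def vjp(g):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(offsets[i], offsets[i + 1])
            return g[tuple(sl)]

        return vjp

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        parents=tuple((t, make_vjp(i)) for i, t in enumerate(tensors)),
    )


def pad2d(a, pt: int, pb: int, pl: int, pr: int) -> Tensor:
    """Zero-pad the last two axes; adjoint is cropping."""
    a = astensor(a)
    widths = [(0, 0)] * (a.data.ndim - 2) + [(pt, pb), (pl, pr)]
    out = np.pad(a.data, widths)
    h, w = a.shape[-2], a.shape[-1]

    def vjp(g):
        return g[..., pt : pt + h, pl : pl + w]

    return Tensor(out, parents=((a, vjp),))


def crop2d(a, pt: int, pb: int, pl: int, pr: int) -> Tensor:
    """Crop the last two axes; adjoint is zero-padding."""
    a = astensor(a)
    h, w = a.shape[-2], a.shape[-1]
    sl = (..., slice(pt, h - pb or None), slice(pl, w - pr or None))

    def vjp(g):
        out = np.zeros(a.shape, dtype=g.dtype)
        out[sl] = g
        return out

    return Tensor(a.data[sl], parents=((a, vjp),))


def matmul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    ad, bd = a.data, b.data
    return Tensor(
        ad @ bd,
        parents=(
            (a, lambda g: g @ np.conj(bd).swapaxes(-1, -2)),
            (b, lambda g: np.conj(ad).swapaxes(-1, -2) @ g),
        ),
    )


# ---------------------------------------------------------------------------
# convolution and resampling (real arrays, layout (C, H, W))
# ---------------------------------------------------------------------------

def conv2d(x, weight, bias=None, padding: int | None = None) -> Tensor:
    """2-D 'same' convolution (cross-correlation) with zero padding.

    ``x``: (Cin, H, W); ``weight``: (Cout, Cin, kh, kw); ``bias``: (Cout,).
    Implemented as one (Cout, Cin) matmul per kernel tap over shifted slices,
    which beats an im2col gather at these problem sizes.
    """
    x, weight = astensor(x), astensor(weight)
    cout, cin, kh, kw = weight.shape
    if x.shape[0] != cin:
        raise ValueError(f"conv2d channel mismatch: input {x.shape[0]}, weight {cin}")
    p = (kh - 1) // 2 if padding is None else padding
    xp = np.pad(x.data, ((0, 0), (p, p), (p, p)))
    h, w = x.shape[1], x.shape[2]
    wd = weight.data
    slabs = [
        np.ascontiguousarray(xp[:, di : di + h, dj : dj + w]).reshape(cin, h * w)
        for di in range(kh)
        for dj in range(kw)
    ]
    acc = np.zeros((cout, h * w))
    for idx, (di, dj) in enumerate((i, j) for i in range(kh) for j in range(kw)):
        acc += wd[:, :, di, dj] @ slabs[idx]
    out = acc.reshape(cout, h, w)

    parents = []

    def vjp_x(g):
        g2 = g.reshape(cout, h * w)
        gxp = np.zeros_like(xp)
        for di in range(kh):
            for dj in range(kw):
                gxp[:, di : di + h, dj : dj + w] += (
                    wd[:, :, di, dj].T @ g2
                ).reshape(cin, h, w)
        if p == 0:
            return gxp
        return gxp[:, p:-p, p:-p]

    def vjp_w(g):
        g2 = g.reshape(cout, h * w)
        gw = np.empty_like(wd)
        for idx, (di, dj) in enumerate((i, j) for i in range(kh) for j in range(kw)):
            gw[:, :, di, dj] = g2 @ slabs[idx].T
        return gw

    parents.append((x, vjp_x))
    parents.append((weight, vjp_w))
    if bias is not None:
        bias = astensor(bias)
        out = out + bias.data[:, None, None]
        parents.append((bias, lambda g: g.sum(axis=(1, 2))))
    return Tensor(out, parents=tuple(parents))


def avg_pool2(x) -> Tensor:
    """2x2 average pooling (even spatial dims)."""
    x = astensor(x)
    c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"avg_pool2 needs even spatial dims, got {(h, w)}")
    out = x.data.reshape(c, h // 2, 2, w // 2, 2).mean(axis=(2, 4))

    def vjp(g):
        return np.repeat(np.repeat(g, 2, axis=1), 2, axis=2) * 0.25

    return Tensor(out, parents=((x, vjp),))


def upsample_nearest2(x) -> Tensor:
    """Nearest-neighbour 2x upsampling."""
    x = astensor(x)
    out = np.repeat(np.repeat(x.data, 2, axis=1), 2, axis=2)
    c, h, w = x.shape

    def vjp(g):
        return g.reshape(c, h, 2, w, 2).sum(axis=(2, 4))

    return Tensor(out, parents=((x, vjp),))


def uniform_filter_valid(x, win: int) -> Tensor:
    """Valid-region uniform (box) mean filter over the last two axes.

    Output spatial size shrinks by ``win - 1``; used by the SSIM loss.
    """
    x = astensor(x)
    if x.shape[-1] < win or x.shape[-2] < win:
        raise ValueError(f"window {win} larger than image {x.shape[-2:]}")
    v = sliding_window_view(x.data, (win, win), axis=(-2, -1))
    out = v.mean(axis=(-2, -1))
    scale = 1.0 / (win * win)
    ho, wo = out.shape[-2], out.shape[-1]

    def vjp(g):
        gx = np.zeros(x.shape, dtype=g.dtype)
        for di in range(win):
            for dj in range(win):
                gx[..., di : di + ho, dj : dj + wo] += g * scale
        return gx

    return Tensor(out, parents=((x, vjp),))


# ---------------------------------------------------------------------------
# complex structure
# ---------------------------------------------------------------------------

def real(z) -> Tensor:
    z = astensor(z)
    return Tensor(z.data.real.copy(), parents=((z, lambda g: g.astype(z.dtype)),))


def imag(z) -> Tensor:
    z = astensor(z)
    return Tensor(z.data.imag.copy(), parents=((z, lambda g: (1j * g).astype(z.dtype)),))


def make_complex(re, im) -> Tensor:
    re, im = astensor(re), astensor(im)
    return Tensor(
        re.data + 1j * im.data,
        parents=((re, lambda g: g.real.copy()), (im, lambda g: g.imag.copy())),
    )


def conj(z) -> Tensor:
    z = astensor(z)
    return Tensor(np.conj(z.data), parents=((z, lambda g: np.conj(g)),))


def cabs(z, eps: float = 0.0) -> Tensor:
    """Elementwise magnitude; for complex input the gradient is ``g * z/|z|``.

    ``eps`` regularizes the gradient at the origin (forward pass unaffected).
    """
    z = astensor(z)
    mag = np.abs(z.data)
    if np.iscomplexobj(z.data):
        phase = z.data / np.maximum(mag, eps if eps > 0 else np.finfo(mag.dtype).tiny)
        vjp = lambda g: g * phase
    else:
        sgn = np.sign(z.data)
        vjp = lambda g: g * sgn
    return Tensor(mag, parents=((z, vjp),))


def fft2c_t(z) -> Tensor:
    """Differentiable centered orthonormal 2-D FFT (unitary: adjoint = inverse)."""
    from .. import kspace

    z = astensor(z)
    return Tensor(kspace.fft2c(z.data), parents=((z, lambda g: kspace.ifft2c(g)),))


def ifft2c_t(z) -> Tensor:
    from .. import kspace

    z = astensor(z)
    return Tensor(kspace.ifft2c(z.data), parents=((z, lambda g: kspace.fft2c(g)),))


def pack_channels_t(z) -> Tensor:
    """Differentiable real/imaginary channel packing, (C,H,W) -> (2C,H,W)."""
    return concat([real(z), imag(z)], axis=0)


def unpack_channels_t(t) -> Tensor:
    t = astensor(t)
    n = t.shape[0]
    if n % 2:
        raise ValueError(f"odd channel count {n} on unpack")
    c = n // 2
    return make_complex(t[:c], t[c:])
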