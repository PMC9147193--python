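"""Core k-space numerics for multi-coil Cartesian MRI.

Conventions used throughout the package
---------------------------------------
* Arrays are complex ndarrays laid out as ``(..., rows, cols)``; multi-coil
  data adds a leading coil axis, ``(coils, rows, cols)``.
* Fourier transforms are *centered* (DC at ``rows//2, cols//2``) and
  *orthonormal* (``norm="ortho"``), so ``fft2c`` is unitary and its adjoint
  equals its inverse.  Sampling masks therefore act on a centered spectrum.
* Real/imaginary channel packing concatenates all real channels first, then
  all imaginary channels, along the leading (coil/channel) axis.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "fft2c",
    "ifft2c",
    "rss_combine",
    "pack_channels",
    "unpack_channels",
]


def _check_spatial(x: np.ndarray) -> None:
    if x.ndim < 2:
        raise ValueError(
            f"expected at least 2 spatial dimensions (rows, cols), got shape {x.shape}"
        )


def fft2c(img: np.ndarray) -> np.ndarray:
    """Centered, orthonormal 2-D Fourier transform over the last two axes.

    A constant image of value ``c`` on an ``n x n`` grid maps to a spectrum
    whose single nonzero entry is ``n*c`` at the array center.
    """
    img = np.asarray(img)
    _check_spatial(img)
    x = np.fft.ifftshift(img, axes=(-2, -1))
    k = np.fft.fft2(x, axes=(-2, -1), norm="ortho")
    return np.fft.fftshift(k, axes=(-2, -1))


def ifft2c(k: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fft2c` (also its adjoint, by unitarity)."""
    k = np.asarray(k)
    _check_spatial(k)
    x = np.fft.ifftshift(k, axes=(-2, -1))
    img = np.fft.ifft2(x, axes=(-2, -1), norm="ortho")
    return np.fft.fftshift(img, axes=(-2, -1))


def rss_combine(imgs: np.ndarray, axis: int = -3) -> np.ndarray:
    """Root-sum-of-squares coil combination.

    Pixelwise Euclidean norm over the coil axis; returns a nonnegative real
    array with the coil axis removed.  Invariant to per-coil global phase.
    """
    imgs = np.asarray(imgs)
    if imgs.ndim < 3:
        raise ValueError(f"expected a coil axis, got shape {imgs.shape}")
    if imgs.shape[axis] < 1:
        raise ValueError("empty coil axis")
    return np.sqrt(np.sum(np.abs(imgs) ** 2, axis=axis))


def pack_channels(z: np.ndarray) -> np.ndarray:
    """Split complex coil data into concatenated real/imaginary channels.

    ``(coils, rows, cols)`` complex becomes ``(2*coils, rows, cols)`` real:
    real parts of all coils first, then imaginary parts.  16-coil complex
    data is treated as 32-channel real data.
    """
    z = np.asarray(z)
    if not np.iscomplexobj(z):
        z = z.astype(np.complex128)
    if z.ndim < 3:
        raise ValueError(f"expected (coils, rows, cols), got shape {z.shape}")
    return np.concatenate([z.real, z.imag], axis=-3)


def unpack_channels(t: np.ndarray) -> np.ndarray:
    """Inverse of :func:`pack_channels`; exact round trip."""
    t = np.asarray(t)
    if t.ndim < 3:
        raise ValueError(f"expected (channels, rows, cols), got shape {t.shape}")
    n = t.shape[-3]
    if n % 2 != 0:
        raise ValueError(f"odd channel count {n}: not a packed real/imag array")
    c = n // 2
    re = t[..., :c, :, :]
    im = t[..., c:, :, :]
    return re + 1j * im
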