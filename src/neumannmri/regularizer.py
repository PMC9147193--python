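"""CNN-based regularization blocks for the unrolled reconstruction.

Three modes:

* ``zero`` — R ≡ 0; the unrolled network degenerates to the truncated
  Neumann series for the regularizer-free least-squares problem (useful as a
  closed-form anchor and as the initialization the zero-initialized final
  convolutions realize).
* ``image_only`` — R(x) = CNN_I(x): the standard Neumann-network regularizer
  acting in the image domain.
* ``multi_domain`` — R(x) = CNN_I(x) + F^{-1}(CNN_F(F x)): a parallel pair of
  CNNs, one removing aliasing in the image domain and one interpolating
  missing data in the frequency domain.

Complex arrays enter the CNNs via real/imaginary channel concatenation, so a
C-channel complex input is a 2C-channel real input.
"""

from __future__ import annotations

import numpy as np

from .nn import autodiff as ad
from .nn.autodiff import Tensor
from .nn.layers import Module, UNet, UNetSpec

__all__ = ["Regularizer", "apply_regularizer", "make_regularizer"]

_MODES = ("zero", "image_only", "multi_domain")


class Regularizer(Module):
    """Shape-preserving regularization operator on complex (C, H, W) arrays.

    ``image_net`` / ``freq_net`` take and return channel-packed real arrays
    (2C channels); any callable works, U-Nets in practice.
    """

    def __init__(self, mode: str = "zero", image_net=None, freq_net=None):
        if mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")
        if mode == "image_only" and image_net is None:
            raise ValueError("image_only mode requires image_net")
        if mode == "multi_domain" and (image_net is None or freq_net is None):
            raise ValueError("multi_domain mode requires image_net and freq_net")
        self.mode = mode
        self.image_net = image_net
        self.freq_net = freq_net

    def named_parameters(self, prefix: str = ""):
        for name in ("image_net", "freq_net"):
            net = getattr(self, name)
            if isinstance(net, Module):
                yield from net.named_parameters(prefix=f"{prefix}{name}.")

    def forward(self, x) -> Tensor:
        x = ad.astensor(x)
        if x.data.ndim != 3:
            raise ValueError(f"expected (C, rows, cols), got shape {x.shape}")
        if self.mode == "zero":
            return Tensor(np.zeros_like(x.data))
        out = ad.unpack_channels_t(self.image_net(ad.pack_channels_t(x)))
        if self.mode == "multi_domain":
            fx = ad.fft2c_t(x)
            fk = ad.unpack_channels_t(self.freq_net(ad.pack_channels_t(fx)))
            out = out + ad.ifft2c_t(fk)
        return out


def apply_regularizer(R: Regularizer, x: np.ndarray) -> np.ndarray:
    """Numpy-facing evaluation of a regularizer on a complex image stack."""
    x = np.asarray(x, dtype=np.complex128)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None]
    out = R(Tensor(x)).data
    return out[0] if squeeze else out


def make_regularizer(
    mode: str,
    complex_channels: int,
    rng: np.random.Generator,
    depth: int = 2,
    base: int = 8,
) -> Regularizer:
    """Build a regularizer whose U-Nets match ``complex_channels`` inputs."""
    ch = 2 * complex_channels
    if mode == "zero":
        return Regularizer("zero")
    image_net = UNet(UNetSpec(in_ch=ch, out_ch=ch, depth=depth, base=base), rng)
    if mode == "image_only":
        return Regularizer(mode, image_net=image_net)
    freq_net = UNet(UNetSpec(in_ch=ch, out_ch=ch, depth=depth, base=base), rng)
    return Regularizer(mode, image_net=image_net, freq_net=freq_net)
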