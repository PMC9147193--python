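"""End-to-end trainable reconstruction models.

Three models mirror the methods compared in the experiments:

* :class:`UNetReconstructor` — the image-enhancement baseline: a single U-Net
  refining the zero-filled RSS image (residual, so the untrained network is
  exactly the zero-filled method).
* :class:`NeumannNet` — the standard image-domain Neumann network.  It treats
  parallel data without sensitivity maps (A = M∘F per coil) and regularizes
  the multi-coil image with one CNN per block.
* :class:`MDNNSM` — the multi-domain Neumann network with sensitivity maps:
  a CNN estimates coil maps from the ACS block, the recursion runs in k-space
  with a parallel image-/frequency-domain regularizer, and the skip
  connections accumulate k-space iterates which are combined by RSS.

Every model maps (k-space, mask) to a real magnitude image and is trained
end-to-end with the SSIM loss on that magnitude.  λ is one trainable scalar
per block, initialized to 1.
"""

from __future__ import annotations

import numpy as np

from . import kspace
from .nn import autodiff as ad
from .nn.autodiff import Tensor
from .nn.layers import Module, ModuleList, Parameter, UNet, UNetSpec
from .recon import NeumannConfig, mdnnsm_series_t, neumann_series_t
from .regularizer import make_regularizer
from .sampling import SamplingMask
from .sensitivity import cnn_maps_t

__all__ = ["SensNet", "UNetReconstructor", "NeumannNet", "MDNNSM", "build_model"]

_RSS_EPS = 1e-20  # regularizes the RSS gradient at exact zeros


def _rss_t(x: Tensor) -> Tensor:
    re, im = ad.real(x), ad.imag(x)
    return ad.sqrt(ad.tsum(ad.square(re) + ad.square(im), axis=0) + _RSS_EPS)


def _zero_filled_rss_t(y: Tensor) -> Tensor:
    return _rss_t(ad.ifft2c_t(y))


class SensNet(Module):
    """Residual coil-map estimator: t + UNet(t) on channel-packed coil images.

    The zero-initialized final convolution makes the untrained estimator the
    identity, so CNN maps start exactly at the ACS low-resolution estimate.
    """

    def __init__(self, num_coils: int, rng, depth: int = 2, base: int = 8):
        ch = 2 * num_coils
        self.unet = UNet(UNetSpec(in_ch=ch, out_ch=ch, depth=depth, base=base), rng)

    def forward(self, t):
        return t + self.unet(t)


class _ModelBase(Module):
    def reconstruct(self, y: np.ndarray, mask: SamplingMask) -> np.ndarray:
        """Numpy-facing inference: magnitude image from undersampled k-space."""
        return self.forward(Tensor(np.asarray(y)), mask).data


class UNetReconstructor(_ModelBase):
    """Zero-filled RSS image refined by a single residual U-Net."""

    def __init__(self, rng, depth: int = 2, base: int = 8):
        self.unet = UNet(UNetSpec(in_ch=1, out_ch=1, depth=depth, base=base), rng)

    def forward(self, y: Tensor, mask: SamplingMask) -> Tensor:
        zf = _zero_filled_rss_t(y)
        t = ad.reshape(zf, (1,) + zf.shape)
        out = t + self.unet(t)
        return ad.reshape(out, zf.shape)


def _make_lambdas(num_blocks: int) -> Parameter:
    return Parameter(np.ones(num_blocks + 1))


class NeumannNet(_ModelBase):
    """Image-domain Neumann network without sensitivity maps."""

    def __init__(
        self,
        num_coils: int,
        rng,
        num_blocks: int = 6,
        share_params: bool = False,
        depth: int = 2,
        base: int = 8,
        lambda_on_regularizer: bool = True,
    ):
        self.num_blocks = num_blocks
        self.lambdas = _make_lambdas(num_blocks)
        n_regs = 1 if share_params else num_blocks
        self.regs = ModuleList(
            make_regularizer("image_only", num_coils, rng, depth=depth, base=base)
            for _ in range(n_regs)
        )
        self.lambda_on_regularizer = lambda_on_regularizer

    def _config(self) -> NeumannConfig:
        return NeumannConfig(
            num_blocks=self.num_blocks,
            lambdas=self.lambdas,
            regularizer=list(self.regs),
            accumulate_domain="image",
            lambda_on_regularizer=self.lambda_on_regularizer,
        )

    def forward(self, y: Tensor, mask: SamplingMask) -> Tensor:
        xhat = neumann_series_t(y, mask, None, self._config())
        return _rss_t(xhat)


class MDNNSM(_ModelBase):
    """Multi-domain Neumann network with CNN-estimated sensitivity maps."""

    def __init__(
        self,
        num_coils: int,
        rng,
        num_blocks: int = 6,
        share_params: bool = False,
        depth: int = 2,
        base: int = 8,
        lambda_on_regularizer: bool = True,
        learn_maps: bool = True,
    ):
        self.num_coils = num_coils
        self.num_blocks = num_blocks
        self.lambdas = _make_lambdas(num_blocks)
        self.sens = SensNet(num_coils, rng, depth=depth, base=base) if learn_maps else None
        n_regs = 1 if share_params else num_blocks
        self.regs = ModuleList(
            make_regularizer("multi_domain", 1, rng, depth=depth, base=base)
            for _ in range(n_regs)
        )
        self.lambda_on_regularizer = lambda_on_regularizer

    def estimate_maps_t(self, y: Tensor, mask: SamplingMask) -> Tensor:
        if self.sens is not None:
            return cnn_maps_t(y, mask, self.sens)
        # non-learned alternative: eps-normalized ACS low-resolution maps
        return cnn_maps_t(y, mask, lambda t: t)

    def forward(self, y: Tensor, mask: SamplingMask) -> Tensor:
        if y.shape[0] != self.num_coils:
            raise ValueError(f"model built for {self.num_coils} coils, got {y.shape[0]}")
        maps = self.estimate_maps_t(y, mask)
        cfg = NeumannConfig(
            num_blocks=self.num_blocks,
            lambdas=self.lambdas,
            regularizer=list(self.regs),
            accumulate_domain="kspace",
            lambda_on_regularizer=self.lambda_on_regularizer,
        )
        khat = mdnnsm_series_t(y, mask, maps, cfg)
        return _rss_t(ad.ifft2c_t(khat))


def zero_filled_reconstruct(y: np.ndarray) -> np.ndarray:
    return kspace.rss_combine(kspace.ifft2c(np.asarray(y)))


def build_model(
    name: str,
    num_coils: int,
    seed: int = 0,
    num_blocks: int = 6,
    share_params: bool = False,
    depth: int = 2,
    base: int = 8,
) -> _ModelBase:
    """Factory for the trainable models (``unet``, ``neumann``, ``mdnnsm``)."""
    rng = np.random.default_rng(seed)
    if name == "unet":
        return UNetReconstructor(rng, depth=depth, base=base)
    if name == "neumann":
        return NeumannNet(num_coils, rng, num_blocks=num_blocks,
                          share_params=share_params, depth=depth, base=base)
    if name == "mdnnsm":
        return MDNNSM(num_coils, rng, num_blocks=num_blocks,
                      share_params=share_params, depth=depth, base=base)
    raise ValueError(f"unknown model {name!r}; expected unet|neumann|mdnnsm")
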