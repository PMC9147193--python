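"""Coil sensitivity map estimation.

Each receiver coil sees the object through a smooth complex spatial weighting
S_c; the forward model of parallel imaging is A = M∘F∘S.  Two estimators are
provided, both driven by the fully sampled ACS block at the center of k-space:

* :func:`acs_lowres_maps` — the classical non-learned estimate: zero-fill
  everything outside the ACS block, inverse-transform each coil, and divide by
  the root-sum-of-squares image.  This is the low-resolution self-calibration
  that eigen-based methods (ESPIRiT) refine, and serves as the non-learned
  comparator here.
* :func:`cnn_maps` — the learned estimate: the same ACS zero-filled coil
  images, packed into real/imaginary channels, are refined by a CNN before
  the pixelwise RSS normalization.

Maps are normalized so that sum_c |S_c|^2 == 1 wherever there is signal, which
makes the conjugate combine sum_c conj(S_c)·(·) an exact left inverse of the
coil expansion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import kspace
from .nn import autodiff as ad
from .nn.autodiff import Tensor
from .sampling import SamplingMask, acs_mask, apply_mask

__all__ = [
    "SensitivityMaps",
    "apply_maps",
    "reduce_maps",
    "normalize_maps",
    "acs_zero_filled",
    "acs_lowres_maps",
    "cnn_maps",
    "cnn_maps_t",
]

# maps are zeroed where the RSS falls below this fraction of its maximum,
# preventing division blow-up in signal-free background
RSS_THRESHOLD_REL = 1e-3


@dataclass
class SensitivityMaps:
    """Complex per-coil spatial profiles, (coils, rows, cols)."""

    data: np.ndarray
    normalized: bool = True

    @property
    def num_coils(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self):
        return self.data.shape


def _check_pair(S: SensitivityMaps, x: np.ndarray, spatial_only: bool) -> None:
    if spatial_only:
        if x.shape != S.data.shape[-2:]:
            raise ValueError(f"shape mismatch: image {x.shape}, maps {S.data.shape}")
    elif x.shape != S.data.shape:
        raise ValueError(f"shape mismatch: coil images {x.shape}, maps {S.data.shape}")


def apply_maps(S: SensitivityMaps, x: np.ndarray) -> np.ndarray:
    """Coil expansion: coil c of the output is S_c ⊙ x."""
    x = np.asarray(x)
    _check_pair(S, x, spatial_only=True)
    return S.data * x[None]


def reduce_maps(S: SensitivityMaps, imgs: np.ndarray) -> np.ndarray:
    """Conjugate coil combine sum_c conj(S_c) ⊙ img_c.

    The adjoint of :func:`apply_maps`, and its exact left inverse when the
    maps are normalized.
    """
    imgs = np.asarray(imgs)
    _check_pair(S, imgs, spatial_only=False)
    return np.sum(np.conj(S.data) * imgs, axis=0)


def normalize_maps(data: np.ndarray, rel_threshold: float = RSS_THRESHOLD_REL) -> np.ndarray:
    """Divide pixelwise by the coil RSS; zero where RSS is below threshold."""
    rss = np.sqrt(np.sum(np.abs(data) ** 2, axis=0))
    thr = rel_threshold * rss.max() if rss.max() > 0 else np.inf
    safe = np.where(rss > thr, rss, 1.0)
    out = np.where(rss[None] > thr, data / safe[None], 0.0)
    return out


def acs_zero_filled(y: np.ndarray, m: SamplingMask) -> np.ndarray:
    """Per-coil IFT of the ACS-masked k-space (the estimator input)."""
    macs = acs_mask(m)
    if macs.num_acs < 1:
        raise ValueError("mask has an empty ACS block")
    return kspace.ifft2c(apply_mask(np.asarray(y), macs))


def acs_lowres_maps(y: np.ndarray, m: SamplingMask) -> SensitivityMaps:
    """Low-resolution self-calibrated maps from the ACS block.

    Invariant to positive rescaling of ``y`` (maps are ratios), and exact for
    spatially constant true maps since low-pass truncation of a constant
    profile leaves it constant.
    """
    imgs = acs_zero_filled(y, m)
    return SensitivityMaps(normalize_maps(imgs), normalized=True)


def cnn_maps_t(y, m: SamplingMask, net, eps: float = 1e-12) -> Tensor:
    """Differentiable CNN map estimation (the learned path).

    The ACS zero-filled coil images are split into real/imaginary channels,
    refined by ``net`` (2·coils channels in and out), recombined to complex,
    and normalized pixelwise by the RSS.  With ``net`` the identity this
    reduces exactly to :func:`acs_lowres_maps` (up to the eps-regularized
    normalization used for differentiability).
    """
    y_t = ad.astensor(y)
    macs = acs_mask(m)
    if macs.num_acs < 1:
        raise ValueError("mask has an empty ACS block")
    zf = ad.ifft2c_t(y_t * macs.as_array())
    packed = ad.pack_channels_t(zf)
    refined = net(packed)
    if refined.shape[0] != packed.shape[0]:
        raise ValueError(
            f"map estimator returned {refined.shape[0]} channels, expected {packed.shape[0]}"
        )
    c = refined.shape[0] // 2
    re, im = refined[:c], refined[c:]
    rss2 = ad.tsum(ad.square(re) + ad.square(im), axis=0, keepdims=True)
    inv = (rss2 + eps) ** (-0.5)
    return ad.make_complex(re * inv, im * inv)


def cnn_maps(y: np.ndarray, m: SamplingMask, net) -> SensitivityMaps:
    """Numpy-facing wrapper around :func:`cnn_maps_t`."""
    y = np.asarray(y)
    maps = cnn_maps_t(Tensor(y), m, net).data
    return SensitivityMaps(maps, normalized=True)
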