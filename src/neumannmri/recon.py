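"""Unrolled Neumann-series reconstruction.

The acquisition is y = A x + ε with A = M∘F∘S (mask, Fourier, coil maps).
Gradient descent on the regularized least-squares objective, truncated after
N steps and accumulated, is the Neumann network:

    x_0 = λ A^H y
    x_j = x_{j-1} − λ A^H A x_{j-1} − λ R(x_{j-1})
    x̂  = Σ_{j=0}^{N} x_j

With R ≡ 0 this is the truncated Neumann series for the normal equations,
whose closed forms (geometric series on a full mask, pseudo-inverse in the
limit) anchor the implementation.  The printed recursion in the source
literature omits λ on the regularizer term; that variant is available via
``lambda_on_regularizer=False``.

The multi-domain variant with sensitivity maps (MDNNSM) runs the same
recursion in k-space by applying F∘S to both sides:

    k_0 = λ M y
    k_j = k_{j-1} − λ M k_{j-1} − λ F S R(S^H F^{-1} k_{j-1})
    k̂  = Σ_j k_j,    x̂ = RSS(F^{-1} k̂)

For single-coil data (S ≡ 1) the two recursions are exactly Fourier
transforms of each other; for multi-coil data S S^H is a projection rather
than the identity and the k-space form is the one defined above (faithful to
its definition, not an algebraic identity).

The operator written A^{-1} in the source derivation is non-square and
non-invertible; it is implemented as the adjoint A^H = S^H∘F^{-1}∘M, the
gradient of the data-fidelity term.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from . import kspace
from .nn import autodiff as ad
from .nn.autodiff import Tensor
from .regularizer import Regularizer
from .sampling import SamplingMask, apply_mask
from .sensitivity import SensitivityMaps, apply_maps, reduce_maps

__all__ = [
    "ForwardModel",
    "NeumannConfig",
    "ReconState",
    "forward_apply",
    "forward_adjoint",
    "data_consistency_block",
    "neumann_reconstruct",
    "mdnnsm_reconstruct",
    "neumann_series_t",
    "mdnnsm_series_t",
]


@dataclass
class ForwardModel:
    """A = M∘F∘S.  With ``maps is None`` the model runs in no-maps mode:
    the operator acts per coil (A = M∘F) on a multi-coil image, which is how
    the image-domain Neumann baseline treats parallel data without
    sensitivity maps."""

    mask: SamplingMask
    maps: Optional[SensitivityMaps] = None


@dataclass
class NeumannConfig:
    """Configuration of the unrolled recursion.

    ``lambdas`` holds N+1 per-block scalars (λ_0 scales the initial term);
    they are trainable in the model classes and default to 1.  ``regularizer``
    is a single block (shared parameters across iterations) or a sequence of
    N blocks (unshared).
    """

    num_blocks: int = 6
    lambdas: Union[float, Sequence, None] = None
    regularizer: Union[Regularizer, Sequence[Regularizer], None] = None
    accumulate_domain: str = "image"
    lambda_on_regularizer: bool = True

    def __post_init__(self):
        if self.num_blocks < 0:
            raise ValueError(f"num_blocks must be >= 0, got {self.num_blocks}")
        if self.accumulate_domain not in ("image", "kspace"):
            raise ValueError(
                f"accumulate_domain must be 'image' or 'kspace', got {self.accumulate_domain!r}"
            )

    def lambda_at(self, j: int):
        """λ for block j (j = 0 is the initial term)."""
        if self.lambdas is None:
            return 1.0
        if np.isscalar(self.lambdas):
            return self.lambdas
        lams = self.lambdas
        if isinstance(lams, Tensor):
            return lams[j] if lams.data.ndim else lams
        return lams[j]

    def regularizer_at(self, j: int) -> Regularizer:
        """Regularizer for block j (1-based); shared blocks return the same object."""
        if self.regularizer is None:
            return _ZERO
        if isinstance(self.regularizer, Regularizer) or callable(self.regularizer):
            return self.regularizer
        return self.regularizer[(j - 1) % len(self.regularizer)]


_ZERO = Regularizer("zero")


@dataclass
class ReconState:
    """Per-iteration bookkeeping: iterate j, its value, and the running sum."""

    iterates: list = field(default_factory=list)
    accumulator: Optional[np.ndarray] = None
    block_index: int = -1

    def record(self, j: int, iterate: np.ndarray, acc: np.ndarray):
        self.iterates.append(np.array(iterate, copy=True))
        self.accumulator = np.array(acc, copy=True)
        self.block_index = j


# ---------------------------------------------------------------------------
# forward operator (numpy surface)
# ---------------------------------------------------------------------------

def forward_apply(A: ForwardModel, x: np.ndarray) -> np.ndarray:
    """y = M F S x (noiseless forward model)."""
    x = np.asarray(x)
    coils = apply_maps(A.maps, x) if A.maps is not None else x
    return apply_mask(kspace.fft2c(coils), A.mask)


def forward_adjoint(A: ForwardModel, y: np.ndarray) -> np.ndarray:
    """A^H y = S^H F^{-1} M y."""
    y = np.asarray(y)
    imgs = kspace.ifft2c(apply_mask(y, A.mask))
    return reduce_maps(A.maps, imgs) if A.maps is not None else imgs


def data_consistency_block(k: np.ndarray, m: SamplingMask, lam: float) -> np.ndarray:
    """(I − λM) k: scales acquired columns by (1 − λ), keeps the rest."""
    return np.asarray(k) - lam * apply_mask(k, m)


# ---------------------------------------------------------------------------
# differentiable operator pieces (Tensor path shared by inference & training)
# ---------------------------------------------------------------------------

def _mask_mul(k: Tensor, m: SamplingMask) -> Tensor:
    return k * m.as_array()


def _maps_tensor(maps) -> Optional[Tensor]:
    if maps is None:
        return None
    if isinstance(maps, Tensor):
        return maps
    if isinstance(maps, SensitivityMaps):
        return Tensor(maps.data)
    return Tensor(np.asarray(maps))


def _apply_maps_t(S: Optional[Tensor], x: Tensor) -> Tensor:
    return x if S is None else S * x


def _reduce_maps_t(S: Optional[Tensor], imgs: Tensor) -> Tensor:
    if S is None:
        return imgs
    return ad.tsum(ad.conj(S) * imgs, axis=0)


def _forward_apply_t(x: Tensor, mask: SamplingMask, S: Optional[Tensor]) -> Tensor:
    return _mask_mul(ad.fft2c_t(_apply_maps_t(S, x)), mask)


def _forward_adjoint_t(y: Tensor, mask: SamplingMask, S: Optional[Tensor]) -> Tensor:
    return _reduce_maps_t(S, ad.ifft2c_t(_mask_mul(y, mask)))


def _check_finite(x: Tensor, j: int):
    if not np.all(np.isfinite(x.data)):
        raise FloatingPointError(f"non-finite iterate at block {j}")


def neumann_series_t(
    y,
    mask: SamplingMask,
    maps,
    cfg: NeumannConfig,
    state: Optional[ReconState] = None,
) -> Tensor:
    """Image-domain truncated Neumann recursion; returns the accumulation x̂.

    With ``maps is None`` the iterate is a multi-coil image and A = M∘F acts
    per coil.  Linear in y when the regularizer is zero.
    """
    y_t = ad.astensor(y)
    S = _maps_tensor(maps)
    x = ad.astensor(cfg.lambda_at(0)) * _forward_adjoint_t(y_t, mask, S)
    acc = x
    if state is not None:
        state.record(0, x.data, acc.data)
    for j in range(1, cfg.num_blocks + 1):
        lam = ad.astensor(cfg.lambda_at(j))
        r_in = x if S is None else ad.reshape(x, (1,) + x.shape)
        r = cfg.regularizer_at(j)(r_in)
        if S is not None:
            r = ad.reshape(r, x.shape)
        grad = _forward_adjoint_t(_forward_apply_t(x, mask, S), mask, S)
        reg = lam * r if cfg.lambda_on_regularizer else r
        x = x - lam * grad - reg
        _check_finite(x, j)
        acc = acc + x
        if state is not None:
            state.record(j, x.data, acc.data)
    return acc


def mdnnsm_series_t(
    y,
    mask: SamplingMask,
    maps,
    cfg: NeumannConfig,
    state: Optional[ReconState] = None,
) -> Tensor:
    """K-space recursion with skip-connection accumulation; returns k̂.

    The regularizer acts on the coil-combined image S^H F^{-1} k and its
    output is re-expanded by F∘S; the data-consistency block (I − λM) acts
    directly on k-space.
    """
    y_t = ad.astensor(y)
    S = _maps_tensor(maps)
    if S is None:
        raise ValueError("the k-space recursion requires sensitivity maps")
    k = ad.astensor(cfg.lambda_at(0)) * _mask_mul(y_t, mask)
    acc = k
    if state is not None:
        state.record(0, k.data, acc.data)
    for j in range(1, cfg.num_blocks + 1):
        lam = ad.astensor(cfg.lambda_at(j))
        x = _reduce_maps_t(S, ad.ifft2c_t(k))
        r = cfg.regularizer_at(j)(ad.reshape(x, (1,) + x.shape))
        r = ad.reshape(r, x.shape)
        back = ad.fft2c_t(_apply_maps_t(S, r))
        reg = lam * back if cfg.lambda_on_regularizer else back
        k = k - lam * _mask_mul(k, mask) - reg
        _check_finite(k, j)
        acc = acc + k
        if state is not None:
            state.record(j, k.data, acc.data)
    return acc


# ---------------------------------------------------------------------------
# numpy-facing reconstruction entry points
# ---------------------------------------------------------------------------

def neumann_reconstruct(
    y: np.ndarray,
    A: ForwardModel,
    cfg: NeumannConfig,
    return_state: bool = False,
):
    """Image-domain Neumann reconstruction; returns the accumulated x̂.

    Output is a complex image (rows, cols) when ``A.maps`` is set, or a
    multi-coil complex image in no-maps mode.
    """
    if cfg.accumulate_domain != "image":
        raise ValueError("neumann_reconstruct requires accumulate_domain='image'")
    state = ReconState() if return_state else None
    xhat = neumann_series_t(np.asarray(y), A.mask, A.maps, cfg, state=state).data
    return (xhat, state) if return_state else xhat


def mdnnsm_reconstruct(
    y: np.ndarray,
    A: ForwardModel,
    cfg: NeumannConfig,
    return_state: bool = False,
):
    """K-space-accumulated reconstruction; returns the real RSS image x̂."""
    if cfg.accumulate_domain != "kspace":
        raise ValueError("mdnnsm_reconstruct requires accumulate_domain='kspace'")
    state = ReconState() if return_state else None
    khat = mdnnsm_series_t(np.asarray(y), A.mask, A.maps, cfg, state=state).data
    xhat = kspace.rss_combine(kspace.ifft2c(khat))
    return (xhat, state) if return_state else xhat
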