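"""Reconstruction quality metrics and the SSIM training loss.

NMSE is ``||xhat - xref||^2 / ||xref||^2`` on real magnitude images.  SSIM is
the mean local structural similarity over a 7x7 uniform window, computed on
valid (fully inside) windows with the standard constants K1=0.01, K2=0.03 and
sample-covariance normalization; it equals 1 iff the images are identical and
is symmetric in its two arguments (NMSE is not: the reference normalizes it).

Evaluation follows the fastMRI convention: NMSE on physical-scale magnitude
images and SSIM with the per-slice reference range as ``data_range``, which
makes scores invariant to joint positive rescaling of reconstruction and
reference.  The 12-bit [0, 4095] min-max rescale used for display and
difference maps is available as :func:`normalize_for_eval` and as an
``evaluate_images`` option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import autodiff as ad
from .nn.autodiff import Tensor

__all__ = [
    "nmse",
    "ssim",
    "ssim_t",
    "ssim_loss",
    "normalize_for_eval",
    "evaluate_images",
    "EvalReport",
    "SSIM_WINDOW",
    "EVAL_RANGE",
]

SSIM_WINDOW = 7
EVAL_RANGE = 4095.0
_K1, _K2 = 0.01, 0.03


def nmse(xhat: np.ndarray, xref: np.ndarray) -> float:
    """Normalized mean squared error (0 for identity, 1 for zero prediction)."""
    xhat, xref = np.asarray(xhat, float), np.asarray(xref, float)
    if xhat.shape != xref.shape:
        raise ValueError(f"shape mismatch: {xhat.shape} vs {xref.shape}")
    denom = float(np.sum(xref**2))
    if denom == 0.0:
        raise ValueError("reference image has zero norm")
    return float(np.sum((xhat - xref) ** 2)) / denom


def ssim_t(x, y, data_range: float, win: int = SSIM_WINDOW) -> Tensor:
    """Differentiable mean SSIM over valid uniform windows (Tensor scalar)."""
    x, y = ad.astensor(x), ad.astensor(y)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if data_range <= 0:
        raise ValueError(f"data_range must be positive, got {data_range}")
    c1 = (_K1 * data_range) ** 2
    c2 = (_K2 * data_range) ** 2
    n = win * win
    cov_norm = n / (n - 1)  # sample covariance

    ux = ad.uniform_filter_valid(x, win)
    uy = ad.uniform_filter_valid(y, win)
    uxx = ad.uniform_filter_valid(x * x, win)
    uyy = ad.uniform_filter_valid(y * y, win)
    uxy = ad.uniform_filter_valid(x * y, win)
    vx = (uxx - ux * ux) * cov_norm
    vy = (uyy - uy * uy) * cov_norm
    vxy = (uxy - ux * uy) * cov_norm

    a1 = 2.0 * ux * uy + c1
    a2 = 2.0 * vxy + c2
    b1 = ux * ux + uy * uy + c1
    b2 = vx + vy + c2
    return ad.tmean((a1 * a2) / (b1 * b2))


def ssim(
    xhat: np.ndarray, xref: np.ndarray, data_range: float | None = None,
    win: int = SSIM_WINDOW,
) -> float:
    """Structural similarity of two real images (scalar in [-1, 1])."""
    xhat = np.asarray(xhat, float)
    xref = np.asarray(xref, float)
    if data_range is None:
        data_range = float(xref.max() - xref.min())
        if data_range == 0:
            raise ValueError("reference has zero dynamic range; pass data_range")
    return float(ssim_t(xhat, xref, data_range=data_range, win=win).item())


def ssim_loss(pred, target, data_range: float | None = None) -> Tensor:
    """1 − SSIM(pred, target), differentiable w.r.t. ``pred``.

    ``pred`` is the real magnitude output of a model (Tensor); ``target`` the
    real ground-truth image.  Loss lies in [0, 2].
    """
    target = np.asarray(target.data if isinstance(target, Tensor) else target, float)
    if data_range is None:
        data_range = float(target.max() - target.min())
        if data_range == 0:
            raise ValueError("target has zero dynamic range")
    return 1.0 - ssim_t(pred, Tensor(target), data_range=data_range)


def normalize_for_eval(img: np.ndarray, hi: float = EVAL_RANGE) -> np.ndarray:
    """Min-max rescale an image to [0, hi] (the 12-bit display convention)."""
    img = np.asarray(img, float)
    lo, up = float(img.min()), float(img.max())
    if up == lo:
        raise ValueError("constant image: zero dynamic range")
    return (img - lo) / (up - lo) * hi


@dataclass
class EvalReport:
    """Per-slice and aggregate NMSE/SSIM for one method at one mask setting."""

    method: str
    acceleration: int
    acs_fraction: float
    per_slice: list = field(default_factory=list)

    @property
    def mean_nmse(self) -> float:
        return float(np.mean([s["nmse"] for s in self.per_slice]))

    @property
    def mean_ssim(self) -> float:
        return float(np.mean([s["ssim"] for s in self.per_slice]))

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "accel": self.acceleration,
            "acs": self.acs_fraction,
            "per_slice": self.per_slice,
            "mean_nmse": self.mean_nmse,
            "mean_ssim": self.mean_ssim,
        }


def evaluate_images(
    recons,
    refs,
    method: str = "",
    acceleration: int = 0,
    acs_fraction: float = 0.0,
    normalize: bool = False,
) -> EvalReport:
    """Score reconstructions against references slice by slice.

    With ``normalize=True`` both images are min-max rescaled to [0, 4095]
    first (the display convention); by default metrics are computed on the
    physical scale with the reference range as the SSIM data range.  A
    constant (zero-dynamic-range) reference is rejected either way.
    """
    report = EvalReport(method, acceleration, acs_fraction)
    for i, (rec, ref) in enumerate(zip(recons, refs)):
        if normalize:
            rec, ref = normalize_for_eval(rec), normalize_for_eval(ref)
            dr = EVAL_RANGE
        else:
            dr = float(np.max(ref) - np.min(ref))
            if dr == 0:
                raise ValueError("constant reference image: zero dynamic range")
        report.per_slice.append(
            {"slice": i, "nmse": nmse(rec, ref), "ssim": ssim(rec, ref, data_range=dr)}
        )
    return report
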