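"""Equi-spaced Cartesian undersampling masks with a centered ACS block.

The mask is a binary vector over k-space columns (the phase-encode axis),
broadcast over rows and coils, producing the vertical-stripe sampling
pattern of regular (equi-spaced) undersampling.  The auto-calibration
signal (ACS) is a contiguous, centered, fully sampled block of low-frequency
columns used to calibrate sensitivity maps and GRAPPA kernels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["SamplingMask", "make_equispaced_mask", "apply_mask", "acs_mask"]


@dataclass(frozen=True)
class SamplingMask:
    """Binary column-selection operator with an identified ACS sub-block.

    Attributes
    ----------
    mask : (num_cols,) bool array; True where the column is acquired.
    acceleration : nominal undersampling factor of the equi-spaced part.
    acs_fraction : fraction of columns in the ACS block.
    acs_start, acs_end : half-open column range [acs_start, acs_end) of the
        centered ACS block.  Every ACS column is sampled.
    offset : residue class of the equi-spaced columns modulo ``acceleration``.
    """

    mask: np.ndarray
    acceleration: int
    acs_fraction: float
    acs_start: int
    acs_end: int
    offset: int = 0

    @property
    def num_cols(self) -> int:
        return self.mask.shape[0]

    @property
    def num_acs(self) -> int:
        return self.acs_end - self.acs_start

    def as_array(self, dtype=np.float64) -> np.ndarray:
        return self.mask.astype(dtype)


def make_equispaced_mask(
    num_cols: int, acceleration: int, acs_fraction: float, offset: int = 0
) -> SamplingMask:
    """Build an equi-spaced mask: every ``acceleration``-th column plus a
    centered ACS block of ``round(acs_fraction * num_cols)`` columns.

    The standard parameter pairs are (acceleration, ACS fraction) =
    (2, 0.10), (4, 0.08) and (8, 0.04).
    """
    if acceleration < 1:
        raise ValueError(f"acceleration must be >= 1, got {acceleration}")
    if acceleration > num_cols:
        raise ValueError(
            f"acceleration {acceleration} exceeds number of columns {num_cols}"
        )
    if not (0.0 < acs_fraction <= 1.0):
        raise ValueError(f"acs_fraction must be in (0, 1], got {acs_fraction}")
    if acs_fraction * num_cols < 1.0:
        raise ValueError(
            f"acs_fraction {acs_fraction} yields no ACS line on {num_cols} columns"
        )
    if not (0 <= offset < acceleration):
        raise ValueError(f"offset must be in [0, {acceleration}), got {offset}")

    n_acs = max(1, int(round(acs_fraction * num_cols)))
    acs_start = (num_cols - n_acs) // 2
    acs_end = acs_start + n_acs

    mask = np.zeros(num_cols, dtype=bool)
    mask[offset::acceleration] = True
    mask[acs_start:acs_end] = True
    return SamplingMask(
        mask=mask,
        acceleration=acceleration,
        acs_fraction=acs_fraction,
        acs_start=acs_start,
        acs_end=acs_end,
        offset=offset,
    )


def apply_mask(k: np.ndarray, m: SamplingMask) -> np.ndarray:
    """Zero out unsampled columns; sampled columns pass through bit-identically.

    Idempotent: applying the mask twice equals applying it once.
    """
    k = np.asarray(k)
    if k.shape[-1] != m.num_cols:
        raise ValueError(
            f"column count mismatch: data has {k.shape[-1]}, mask has {m.num_cols}"
        )
    out = np.zeros_like(k)
    out[..., m.mask] = k[..., m.mask]
    return out


def acs_mask(m: SamplingMask) -> SamplingMask:
    """Mask selecting only the ACS block (the M_ACS operator).

    Idempotent; with ``acs_fraction == 1`` it equals the full mask.
    """
    mask = np.zeros(m.num_cols, dtype=bool)
    mask[m.acs_start : m.acs_end] = True
    return replace(m, mask=mask)
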