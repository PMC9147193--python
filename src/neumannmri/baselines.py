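"""Classical comparators: zero-filled reconstruction and GRAPPA.

GRAPPA fills each missing k-space column by a coil-weighted linear
interpolation of neighbouring acquired columns; the interpolation kernel is
calibrated by least squares on the fully sampled ACS block, where both the
sources and the targets are known.  Acquired samples are never modified, so
data consistency is exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import kspace
from .sampling import SamplingMask

__all__ = ["GrappaKernel", "zero_filled", "grappa_calibrate", "grappa_reconstruct"]


def zero_filled(y: np.ndarray) -> np.ndarray:
    """RSS of the per-coil IFT of k-space as-is (missing entries at zero)."""
    return kspace.rss_combine(kspace.ifft2c(np.asarray(y)))


@dataclass
class GrappaKernel:
    """Calibrated interpolation weights.

    ``weights[r]`` maps the flattened source vector (coils x kernel_rows x
    n_source_cols) to the target coil values at column offset ``r`` (1..R-1)
    from the preceding acquired equispaced column.
    """

    weights: dict  # r -> (coils, coils * kernel_rows * n_src_cols) complex
    acceleration: int
    kernel_rows: int = 5
    n_src_per_side: int = 2

    @property
    def row_offsets(self) -> np.ndarray:
        h = self.kernel_rows // 2
        return np.arange(-h, self.kernel_rows - h)

    @property
    def col_offsets(self) -> np.ndarray:
        """Source column offsets (multiples of R) relative to the preceding
        acquired column: 2 per side means {-R, 0, +R, +2R}."""
        ns = self.n_src_per_side
        return self.acceleration * np.arange(-(ns - 1), ns + 1)


def _source_matrix(
    y: np.ndarray, t_rows: np.ndarray, t_cols: np.ndarray, r: int,
    row_offsets: np.ndarray, col_offsets: np.ndarray,
) -> np.ndarray:
    """Source matrix for targets at (t_rows, t_cols): shape (n, C*kr*nc).

    Rows wrap circularly; out-of-range source columns contribute zero.
    """
    c, h, w = y.shape
    blocks = []
    base = t_cols - r
    for dr in row_offsets:
        rows = (t_rows + dr) % h
        for dc in col_offsets:
            cols = base + dc
            valid = (cols >= 0) & (cols < w)
            vals = np.zeros((c, t_rows.size), dtype=y.dtype)
            vals[:, valid] = y[:, rows[valid], cols[valid]]
            blocks.append(vals)
    # (n, C * kr * nc) with coil fastest within each (dr, dc) block
    return np.concatenate(blocks, axis=0).T


def grappa_calibrate(
    y_acs: np.ndarray,
    accel: int,
    kernel_rows: int = 5,
    n_src_per_side: int = 2,
    tikhonov: float = 1e-4,
) -> GrappaKernel:
    """Calibrate GRAPPA weights on a fully sampled ACS block (coils, H, W_acs).

    Solves, for each target offset r in 1..accel-1, the damped least squares
    ``min ||sources @ w - targets||^2 + tau ||w||^2`` with
    ``tau = tikhonov * ||S^H S||_2``; ``tikhonov=0`` gives the plain
    (minimum-norm) least-squares solution.
    """
    y_acs = np.asarray(y_acs)
    c, h, w_acs = y_acs.shape
    kern = GrappaKernel({}, accel, kernel_rows, n_src_per_side)
    n_unknowns = c * kernel_rows * len(kern.col_offsets)
    for r in range(1, accel):
        # targets whose every source column lies inside the ACS block
        t_all = np.arange(w_acs)
        src_min = t_all - r + kern.col_offsets.min()
        src_max = t_all - r + kern.col_offsets.max()
        t_valid = t_all[(src_min >= 0) & (src_max < w_acs)]
        n_eq = h * t_valid.size
        if n_eq < n_unknowns:
            span = int(kern.col_offsets.max() - kern.col_offsets.min())
            need = span + int(np.ceil(n_unknowns / h))
            raise ValueError(
                f"ACS too small: {n_eq} calibration equations for {n_unknowns} "
                f"unknowns at offset {r}; need at least {need} ACS columns"
            )
        t_rows = np.repeat(np.arange(h), t_valid.size)
        t_cols = np.tile(t_valid, h)
        S = _source_matrix(y_acs, t_rows, t_cols, r, kern.row_offsets, kern.col_offsets)
        T = y_acs[:, t_rows, t_cols].T  # (n, C)
        if tikhonov > 0:
            G = S.conj().T @ S
            tau = tikhonov * np.linalg.norm(G, 2)
            W = np.linalg.solve(G + tau * np.eye(n_unknowns), S.conj().T @ T)
        else:
            W = np.linalg.lstsq(S, T, rcond=None)[0]
        kern.weights[r] = W.T  # (C_out, n_unknowns)
    return kern


def grappa_reconstruct(
    y: np.ndarray, m: SamplingMask, k: GrappaKernel, return_kspace: bool = False
):
    """Fill missing columns by kernel interpolation; RSS image of the result.

    Acquired columns (equispaced and ACS) pass through bit-identically.
    """
    y = np.asarray(y)
    if y.shape[-1] != m.num_cols:
        raise ValueError("mask/data column mismatch")
    if k.acceleration != m.acceleration:
        raise ValueError(
            f"kernel acceleration {k.acceleration} != mask acceleration {m.acceleration}"
        )
    c, h, w = y.shape
    filled = y.copy()
    rows = np.arange(h)
    for t in np.nonzero(~m.mask)[0]:
        r = (t - m.offset) % m.acceleration
        S = _source_matrix(
            y, rows, np.full(h, t), r, k.row_offsets, k.col_offsets
        )  # (h, K)
        filled[:, :, t] = (S @ k.weights[r].T).T
    img = zero_filled(filled)
    return (img, filled) if return_kspace else img
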