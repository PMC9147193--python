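"""Synthetic multi-coil acquisition simulator.

Generates the statistical structure the reconstruction model assumes:

* piecewise-smooth, real-valued, nonnegative anatomy (random superpositions
  of ellipses, like a magnitude T1 image), values in [0, 1];
* smooth complex per-coil sensitivity profiles — Gaussian magnitude bumps
  centered on a circle around the field of view with gentle linear phase
  ramps, normalized so sum_c |S_c|^2 == 1 everywhere;
* i.i.d. complex Gaussian measurement noise in k-space, equal sigma across
  coils, with per-entry variance E|eps|^2 = sigma^2;
* regular column-wise undersampling with a centered ACS block.

Every scene is deterministic in its seed, so simulator scenes serve as
reproducible fixtures for parameter-recovery tests throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import kspace
from .sampling import SamplingMask, apply_mask, make_equispaced_mask
from .sensitivity import SensitivityMaps, apply_maps

__all__ = [
    "PhantomScene",
    "make_phantom",
    "make_coil_maps",
    "make_scene",
    "simulate_acquisition",
    "make_scene_batch",
]

# default relative noise level: noise sigma as a fraction of the RMS k-space
# magnitude of the clean acquisition (a high-SNR structural scan)
DEFAULT_NOISE_REL = 0.02


@dataclass
class PhantomScene:
    """Ground truth record for one synthetic acquisition."""

    image: np.ndarray  # real, nonnegative, in [0, 1]
    maps: SensitivityMaps
    mask: SamplingMask
    noise_sigma: float
    seed: int

    @property
    def shape(self):
        return self.image.shape

    @property
    def num_coils(self) -> int:
        return self.maps.num_coils


def make_phantom(rows: int, cols: int, num_ellipses: int = 8, seed: int = 0) -> np.ndarray:
    """Random superposition of ellipses, clipped to [0, 1]; deterministic per seed."""
    if rows < 16 or cols < 16:
        raise ValueError(f"phantom dims must be >= 16, got {(rows, cols)}")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:rows, 0:cols]
    yy = (yy - (rows - 1) / 2) / (rows / 2)
    xx = (xx - (cols - 1) / 2) / (cols / 2)
    img = np.zeros((rows, cols))
    for i in range(num_ellipses):
        if i == 0:
            # a large head-like ellipse so the object has connected support
            cy, cx, a, b, theta = 0.0, 0.0, 0.8, 0.7, 0.0
            amp = rng.uniform(0.3, 0.5)
        else:
            cy, cx = rng.uniform(-0.5, 0.5, size=2)
            a, b = rng.uniform(0.08, 0.45, size=2)
            theta = rng.uniform(0, np.pi)
            # positive intensities: anatomy is dark-to-bright, never zero inside
            amp = rng.uniform(0.15, 0.6)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        img[(u / a) ** 2 + (v / b) ** 2 <= 1.0] += amp
    return np.clip(img, 0.0, 1.0)


def object_support(image: np.ndarray, threshold: float = 0.1, erode: int = 2) -> np.ndarray:
    """Boolean mask of the object interior.

    Pixels above ``threshold`` with ``erode`` rounds of binary erosion, so the
    partial-volume boundary ring (where self-calibration ratios are undefined
    in any method) is excluded.
    """
    from scipy.ndimage import binary_erosion

    supp = np.asarray(image) > threshold
    if erode:
        supp = binary_erosion(supp, iterations=erode)
    return supp


def make_coil_maps(rows: int, cols: int, num_coils: int, seed: int = 0) -> SensitivityMaps:
    """Smooth complex coil profiles with pixelwise RSS normalized to 1.

    Gaussian magnitude bumps centered at equally spaced points on a circle
    around the FOV, each with a smooth random linear phase ramp.
    """
    if num_coils < 1:
        raise ValueError("num_coils must be >= 1")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:rows, 0:cols]
    yy = (yy - (rows - 1) / 2) / (rows / 2)
    xx = (xx - (cols - 1) / 2) / (cols / 2)
    radius = 1.3
    width = 1.1
    maps = np.empty((num_coils, rows, cols), dtype=np.complex128)
    for c in range(num_coils):
        ang = 2 * np.pi * c / num_coils + rng.uniform(-0.1, 0.1)
        cy, cx = radius * np.sin(ang), radius * np.cos(ang)
        mag = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * width**2))
        slope = rng.uniform(-0.5, 0.5, size=2)
        phase = slope[0] * yy + slope[1] * xx + rng.uniform(0, 2 * np.pi)
        maps[c] = mag * np.exp(1j * phase)
    rss = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    return SensitivityMaps(maps / rss[None], normalized=True)


def make_scene(
    rows: int = 64,
    cols: int = 64,
    num_coils: int = 4,
    acceleration: int = 4,
    acs_fraction: float = 0.08,
    noise_rel: float = DEFAULT_NOISE_REL,
    num_ellipses: int = 8,
    seed: int = 0,
) -> PhantomScene:
    """Assemble a deterministic scene; sub-seeds derive from ``seed``."""
    ss = np.random.SeedSequence(seed)
    s_img, s_maps, _ = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3))
    image = make_phantom(rows, cols, num_ellipses=num_ellipses, seed=s_img)
    maps = make_coil_maps(rows, cols, num_coils, seed=s_maps)
    mask = make_equispaced_mask(cols, acceleration, acs_fraction)
    clean = kspace.fft2c(apply_maps(maps, image))
    sigma = noise_rel * float(np.sqrt(np.mean(np.abs(clean) ** 2)))
    return PhantomScene(image=image, maps=maps, mask=mask, noise_sigma=sigma, seed=seed)


def simulate_acquisition(scene: PhantomScene):
    """Return (undersampled y, fully sampled y_full) k-space for a scene.

    y_full = F(S x) + sigma * (N + iN)/sqrt(2);  y = M y_full.
    The noise stream is seeded by the scene seed, so acquisitions are
    bit-reproducible.
    """
    clean = kspace.fft2c(apply_maps(scene.maps, scene.image))
    if scene.noise_sigma > 0:
        rng = np.random.default_rng(np.random.SeedSequence(scene.seed).spawn(3)[2])
        noise = scene.noise_sigma / np.sqrt(2.0) * (
            rng.standard_normal(clean.shape) + 1j * rng.standard_normal(clean.shape)
        )
        y_full = clean + noise
    else:
        y_full = clean
    return apply_mask(y_full, scene.mask), y_full


def make_scene_batch(
    num_scenes: int,
    seed: int = 0,
    **scene_kwargs,
) -> list[PhantomScene]:
    """A list of independent scenes with seeds derived from ``seed``."""
    ss = np.random.SeedSequence(seed)
    return [
        make_scene(seed=int(child.generate_state(1)[0] % 2**31), **scene_kwargs)
        for child in ss.spawn(num_scenes)
    ]
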