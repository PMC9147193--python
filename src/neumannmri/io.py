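"""HDF5 volume I/O (fastMRI dialect), checkpoints, and PNG export.

Volumes are stored with datasets named ``kspace`` (slices x coils x rows x
cols, native complex), ``reconstruction_rss`` (slices x rows x cols, real)
and optionally ``sensitivity_maps``; acquisition metadata lives in root
attributes.  A compound (re, im) fallback reader covers files written with a
two-field complex dtype.  Checkpoints are a flat name->array archive with a
JSON config sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import h5py
import numpy as np

__all__ = [
    "VolumeRecord",
    "MissingDatasetError",
    "read_volume",
    "write_volume",
    "scenes_to_volume",
    "save_checkpoint",
    "load_checkpoint",
    "export_png",
    "export_difference_png",
]


class MissingDatasetError(KeyError):
    """A required dataset is absent from an HDF5 file."""


@dataclass
class VolumeRecord:
    """One multi-slice acquisition: k-space plus optional references."""

    kspace: Optional[np.ndarray] = None  # (slices, coils, rows, cols) complex
    reconstruction_rss: Optional[np.ndarray] = None  # (slices, rows, cols)
    sensitivity_maps: Optional[np.ndarray] = None  # (slices, coils, rows, cols)
    attrs: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kspace is not None and self.reconstruction_rss is not None:
            if self.kspace.shape[0] != self.reconstruction_rss.shape[0]:
                raise ValueError("slice count mismatch between kspace and reference")

    @property
    def num_slices(self) -> int:
        for arr in (self.kspace, self.reconstruction_rss):
            if arr is not None:
                return arr.shape[0]
        return 0


def _as_complex(arr: np.ndarray) -> np.ndarray:
    """Accept native complex or a two-field compound (re, im) layout."""
    if np.iscomplexobj(arr):
        return np.asarray(arr)
    if arr.dtype.names and len(arr.dtype.names) == 2:
        a, b = arr.dtype.names
        return arr[a].astype(np.float64) + 1j * arr[b].astype(np.float64)
    return np.asarray(arr)


def read_volume(path) -> VolumeRecord:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        f = h5py.File(path, "r")
    except OSError as e:
        raise OSError(f"not a readable HDF5 file: {path}") from e
    with f:
        rec = VolumeRecord(attrs=dict(f.attrs))
        if "kspace" in f:
            rec.kspace = _as_complex(f["kspace"][()])
        if "reconstruction_rss" in f:
            rec.reconstruction_rss = np.asarray(f["reconstruction_rss"][()])
        if "sensitivity_maps" in f:
            rec.sensitivity_maps = _as_complex(f["sensitivity_maps"][()])
    if rec.kspace is None and rec.reconstruction_rss is None:
        raise MissingDatasetError(
            f"{path} contains neither 'kspace' nor 'reconstruction_rss'"
        )
    return rec


def write_volume(path, rec: VolumeRecord) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        if rec.kspace is not None:
            f.create_dataset("kspace", data=np.asarray(rec.kspace, np.complex128))
        if rec.reconstruction_rss is not None:
            f.create_dataset(
                "reconstruction_rss", data=np.asarray(rec.reconstruction_rss, np.float64)
            )
        if rec.sensitivity_maps is not None:
            f.create_dataset(
                "sensitivity_maps", data=np.asarray(rec.sensitivity_maps, np.complex128)
            )
        for k, v in rec.attrs.items():
            f.attrs[k] = v
    return path


def scenes_to_volume(scenes) -> VolumeRecord:
    """Stack simulator scenes into one volume (fully sampled k-space +
    reference RSS); mask parameters go to attributes so downstream commands
    can rebuild the sampling mask."""
    from . import kspace as ksp
    from .phantom import simulate_acquisition

    kspaces, refs, maps = [], [], []
    for sc in scenes:
        _, y_full = simulate_acquisition(sc)
        kspaces.append(y_full)
        refs.append(ksp.rss_combine(ksp.ifft2c(y_full)))
        maps.append(sc.maps.data)
    first = scenes[0]
    return VolumeRecord(
        kspace=np.stack(kspaces),
        reconstruction_rss=np.stack(refs),
        sensitivity_maps=np.stack(maps),
        attrs={
            "acceleration": first.mask.acceleration,
            "acs_fraction": first.mask.acs_fraction,
            "noise_sigma": float(first.noise_sigma),
            "num_coils": first.num_coils,
        },
    )


def save_checkpoint(path, state: dict, config: dict) -> Path:
    """Flat array archive + human-readable JSON config sidecar."""
    path = Path(path)
    if path.suffix != ".npz":
        path = Path(str(path) + ".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **state)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(config, indent=2, default=float))
    return path


def load_checkpoint(path):
    path = Path(path)
    with np.load(path) as z:
        state = {k: z[k] for k in z.files}
    sidecar = path.with_suffix(".json")
    config = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return state, config


def export_png(path, image: np.ndarray, cmap: str = "gray") -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    plt.imsave(path, np.asarray(image, float), cmap=cmap)
    return path


def export_difference_png(path, recon: np.ndarray, ref: np.ndarray) -> Path:
    """Difference map |reference − reconstruction| after 0-4095 normalization."""
    from .metrics import normalize_for_eval

    diff = np.abs(normalize_for_eval(ref) - normalize_for_eval(recon))
    return export_png(path, diff, cmap="viridis")
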