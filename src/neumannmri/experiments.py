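"""Scaled-down simulation experiments.

The full-scale study (thousands of brain slices, 50-epoch GPU training) is
out of desk-scale reach, so the qualitative comparisons are reproduced on the
simulator at a fixed toy profile: 64x64 scenes, 4 coils, 64 training and 16
validation scenes, 5 epochs of Adam at the standard learning rate, 6 unrolled
blocks, depth-2/width-8 U-Nets.  The quantities of interest are orderings
(multi-domain with maps < image-only unrolled < zero-filled at 4x) and the
monotone degradation of zero-filling with acceleration, not absolute scores.
"""

from __future__ import annotations

import numpy as np

from . import baselines
from .models import build_model
from .phantom import make_scene_batch
from .train import TrainConfig, make_training_samples, train, validation_nmse

__all__ = ["TOY_PROFILE", "MASK_SETTINGS", "scaled_trend_experiment", "zero_fill_sweep"]

# acceleration / ACS-fraction pairs of the standard protocol
MASK_SETTINGS = ((2, 0.10), (4, 0.08), (8, 0.04))

TOY_PROFILE = dict(
    rows=64, cols=64, num_coils=4,
    n_train=64, n_val=16,
    epochs=5, lr=1e-4,
    num_blocks=6, depth=2, base=8,
)


def _datasets(seed: int, acceleration: int, acs_fraction: float, p: dict):
    kw = dict(rows=p["rows"], cols=p["cols"], num_coils=p["num_coils"],
              acceleration=acceleration, acs_fraction=acs_fraction)
    tr = make_training_samples(make_scene_batch(p["n_train"], seed=seed, **kw))
    va = make_training_samples(make_scene_batch(p["n_val"], seed=seed + 1000, **kw))
    return tr, va


def zero_fill_sweep(seed: int = 0, profile: dict | None = None) -> dict:
    """Validation NMSE of zero-filling at the three standard mask settings."""
    p = dict(TOY_PROFILE, **(profile or {}))
    out = {}
    for accel, acs in MASK_SETTINGS:
        _, va = _datasets(seed, accel, acs, p)
        out[accel] = validation_nmse(lambda y, m: baselines.zero_filled(y), va)
    return out


def scaled_trend_experiment(
    seed: int = 0, profile: dict | None = None, verbose: bool = False
) -> dict:
    """Train the multi-domain and image-only unrolled networks at 4x and
    compare mean validation NMSE against zero-filling.

    Returns ``{"zero_filled": ..., "neumann": ..., "mdnnsm": ..., "n_val": ...}``
    where the learned entries are the best-by-validation checkpoints of the
    5-epoch runs.
    """
    p = dict(TOY_PROFILE, **(profile or {}))
    accel, acs = MASK_SETTINGS[1]
    tr, va = _datasets(seed, accel, acs, p)
    results = {"zero_filled": validation_nmse(lambda y, m: baselines.zero_filled(y), va)}
    cfg = TrainConfig(lr=p["lr"], epochs=p["epochs"], seed=seed)
    for name in ("neumann", "mdnnsm"):
        model = build_model(
            name, num_coils=p["num_coils"], seed=seed,
            num_blocks=p["num_blocks"], depth=p["depth"], base=p["base"],
        )
        res = train(model, tr, cfg, val_samples=va, verbose=verbose)
        results[name] = min(res.val_nmse)
    results["n_val"] = p["n_val"]
    return results
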