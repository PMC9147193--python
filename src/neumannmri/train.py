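"""Training loop: SSIM loss, Adam, seeded and deterministic.

The loss is 1 − SSIM between the model's real magnitude output and the
reference magnitude image (the RSS reconstruction of the fully sampled
acquisition), with the per-sample reference maximum as the SSIM data range.
Batch size is 1; samples are visited in a seeded shuffled order.  The
checkpoint kept is the best by mean validation NMSE (last epoch if no
validation set is given).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from . import kspace
from .metrics import evaluate_images, ssim_loss
from .nn.autodiff import Tensor
from .nn.optim import Adam
from .phantom import PhantomScene, simulate_acquisition
from .sampling import SamplingMask

__all__ = [
    "TrainConfig",
    "TrainResult",
    "make_training_samples",
    "train",
    "validation_nmse",
]


@dataclass
class TrainConfig:
    """Training hyperparameters (Adam, lr 1e-4, SSIM loss).

    ``epochs=50`` is the full-scale recipe; the toy simulation profile used
    throughout the test suite runs 5 epochs.
    """

    lr: float = 1e-4
    epochs: int = 5
    batch_size: int = 1
    seed: int = 0
    shuffle: bool = True

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class TrainResult:
    epoch_losses: list = field(default_factory=list)
    step_losses: list = field(default_factory=list)
    val_nmse: list = field(default_factory=list)
    best_state: Optional[dict] = None
    best_epoch: int = -1


def make_training_samples(scenes: list[PhantomScene]) -> list[dict]:
    """(y, mask, target) triples; the target is the fully sampled RSS image."""
    samples = []
    for sc in scenes:
        y, y_full = simulate_acquisition(sc)
        target = kspace.rss_combine(kspace.ifft2c(y_full))
        samples.append({"y": y, "mask": sc.mask, "target": target, "scene": sc})
    return samples


def _model_recon_fn(model) -> Callable[[np.ndarray, SamplingMask], np.ndarray]:
    return lambda y, m: model.reconstruct(y, m)


def validation_nmse(recon_fn, samples: list[dict]) -> float:
    """Mean NMSE over samples after the 0-4095 evaluation normalization."""
    recons = [recon_fn(s["y"], s["mask"]) for s in samples]
    refs = [s["target"] for s in samples]
    return evaluate_images(recons, refs).mean_nmse


def train(
    model,
    train_samples: list[dict],
    cfg: TrainConfig,
    val_samples: Optional[list[dict]] = None,
    verbose: bool = False,
) -> TrainResult:
    """Optimize ``model`` in place; returns the loss history and best state.

    Deterministic given ``cfg.seed`` (single-threaded numpy); non-finite loss
    aborts with the offending epoch/step.
    """
    if not train_samples:
        raise ValueError("empty training set")
    opt = Adam(model.parameters(), lr=cfg.lr)
    order_rng = np.random.default_rng(cfg.seed)
    result = TrainResult()
    best = np.inf
    for epoch in range(cfg.epochs):
        idx = np.arange(len(train_samples))
        if cfg.shuffle:
            order_rng.shuffle(idx)
        epoch_loss = 0.0
        for step, i in enumerate(idx):
            s = train_samples[i]
            opt.zero_grad()
            pred = model(Tensor(s["y"]), s["mask"])
            target = s["target"]
            loss = ssim_loss(pred, target, data_range=float(target.max()))
            lval = float(loss.item())
            if not np.isfinite(lval):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, step {step}"
                )
            loss.backward()
            opt.step()
            result.step_losses.append(lval)
            epoch_loss += lval
        result.epoch_losses.append(epoch_loss / len(idx))
        if val_samples:
            v = validation_nmse(_model_recon_fn(model), val_samples)
            result.val_nmse.append(v)
            if v < best:
                best = v
                result.best_state = model.state_dict()
                result.best_epoch = epoch
        if verbose:
            msg = f"epoch {epoch}: loss {result.epoch_losses[-1]:.4f}"
            if val_samples:
                msg += f", val NMSE {result.val_nmse[-1]:.4f}"
            print(msg)
    if result.best_state is None:
        result.best_state = model.state_dict()
        result.best_epoch = cfg.epochs - 1
    else:
        model.load_state_dict(result.best_state)
    return result
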