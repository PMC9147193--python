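"""Neural-network building blocks: conv layers, instance norm, and the U-Net.

All three learned components of the reconstruction pipeline (the coil-map
estimator and the image-/frequency-domain regularizers) share one U-Net
architecture: 3x3 convolutions, instance normalization, and leaky ReLU with
negative slope 0.2.  The final 1x1 convolution is zero-initialized so every
network starts as the zero (or, with a residual connection, the identity)
map, which makes the unrolled reconstruction equal its regularizer-free
closed form at initialization.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "Parameter",
    "Module",
    "ModuleList",
    "Conv2d",
    "InstanceNorm2d",
    "ConvBlock",
    "UNet",
    "UNetSpec",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float64), requires_grad=True)


class Module:
    """Lightweight container with recursive parameter discovery."""

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Parameter):
                yield key, val
            elif isinstance(val, Module):
                yield from val.named_parameters(prefix=f"{key}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        params = dict(self.named_parameters())
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict key mismatch: {sorted(missing)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


class ModuleList(Module):
    def __init__(self, modules=()):
        self._modules = list(modules)

    def __iter__(self):
        return iter(self._modules)

    def __len__(self):
        return len(self._modules)

    def __getitem__(self, i):
        return self._modules[i]

    def append(self, m):
        self._modules.append(m)

    def named_parameters(self, prefix: str = ""):
        for i, m in enumerate(self._modules):
            yield from m.named_parameters(prefix=f"{prefix}{i}.")


class Conv2d(Module):
    """'Same' 2-D convolution with zero padding and He-style init."""

    def __init__(self, in_ch, out_ch, kernel_size=3, rng=None, zero_init=False, bias=True):
        k = kernel_size
        if zero_init:
            w = np.zeros((out_ch, in_ch, k, k))
        else:
            if rng is None:
                raise ValueError("rng required unless zero_init=True")
            std = np.sqrt(2.0 / (in_ch * k * k))
            w = rng.normal(0.0, std, size=(out_ch, in_ch, k, k))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x):
        return ad.conv2d(x, self.weight, self.bias)


class InstanceNorm2d(Module):
    """Per-channel spatial normalization (no affine parameters)."""

    def __init__(self, eps: float = 1e-5):
        self.eps = eps

    def forward(self, x):
        mu = ad.tmean(x, axis=(1, 2), keepdims=True)
        xc = x - mu
        var = ad.tmean(ad.square(xc), axis=(1, 2), keepdims=True)
        return xc / ad.sqrt(var + self.eps)


class ConvBlock(Module):
    """Two (conv -> instance norm -> leaky ReLU) stages."""

    def __init__(self, in_ch, out_ch, rng, slope=0.2):
        self.conv1 = Conv2d(in_ch, out_ch, rng=rng)
        self.conv2 = Conv2d(out_ch, out_ch, rng=rng)
        self.norm1 = InstanceNorm2d()
        self.norm2 = InstanceNorm2d()
        self.slope = slope

    def forward(self, x):
        x = ad.leaky_relu(self.norm1(self.conv1(x)), self.slope)
        x = ad.leaky_relu(self.norm2(self.conv2(x)), self.slope)
        return x


class UNetSpec:
    """Hyperparameters of the shared U-Net architecture.

    ``depth`` pooling stages and ``base`` first-level feature maps; width
    doubles per level.  ``depth=4, base=32`` is a full-scale configuration;
    the toy simulation profile used by the test suite runs ``depth=2, base=8``.
    """

    def __init__(self, in_ch=2, out_ch=2, depth=2, base=8, slope=0.2):
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.depth = depth
        self.base = base
        self.slope = slope

    def to_dict(self):
        return dict(in_ch=self.in_ch, out_ch=self.out_ch, depth=self.depth,
                    base=self.base, slope=self.slope)

    @classmethod
    def from_dict(cls, d):
        return cls(**d)


class UNet(Module):
    """Encoder-decoder with skip connections on (C, H, W) real arrays.

    Odd spatial sizes are zero-padded symmetrically to the next multiple of
    ``2**depth`` and cropped back on output, so spatial shape is preserved.
    """

    def __init__(self, spec: UNetSpec, rng: np.random.Generator):
        self.spec = spec
        d, b = spec.depth, spec.base
        downs = [ConvBlock(spec.in_ch, b, rng, spec.slope)]
        for lev in range(d):
            downs.append(ConvBlock(b * 2**lev, b * 2 ** (lev + 1), rng, spec.slope))
        self.down = ModuleList(downs)
        self.reduce = ModuleList(
            Conv2d(b * 2 ** (d - lev), b * 2 ** (d - lev - 1), kernel_size=1, rng=rng)
            for lev in range(d)
        )
        self.up = ModuleList(
            ConvBlock(b * 2 ** (d - lev), b * 2 ** (d - lev - 1), rng, spec.slope)
            for lev in range(d)
        )
        self.final = Conv2d(b, spec.out_ch, kernel_size=1, zero_init=True)

    def forward(self, x):
        if x.shape[0] != self.spec.in_ch:
            raise ValueError(
                f"expected {self.spec.in_ch} input channels, got {x.shape[0]}"
            )
        m = 2**self.spec.depth
        h, w = x.shape[-2], x.shape[-1]
        ph, pw = (-h) % m, (-w) % m
        pads = (ph // 2, ph - ph // 2, pw // 2, pw - pw // 2)
        if any(pads):
            x = ad.pad2d(x, *pads)

        skips = []
        t = x
        for lev, blk in enumerate(self.down):
            t = blk(t)
            if lev < self.spec.depth:
                skips.append(t)
                t = ad.avg_pool2(t)
        for lev in range(self.spec.depth):
            t = ad.upsample_nearest2(t)
            t = self.reduce[lev](t)
            t = ad.concat([skips.pop(), t], axis=0)
            t = self.up[lev](t)
        t = self.final(t)
        out = ad.crop2d(t, *pads) if any(pads) else t
        if not np.all(np.isfinite(out.data)):
            raise FloatingPointError("non-finite U-Net output")
        return out
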