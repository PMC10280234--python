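"""The channel-attention-retention super-resolution network.

The network is a shallow residual-in-residual CNN for pathology-image
super-resolution. A small stack of channel-attention retention blocks
(CARBs) transforms features extracted by a single head convolution; a
long skip adds the head features back before sub-pixel upsampling, so
the body only has to learn the high-frequency residual:

    F_0  = head(normalize(I_LR))
    F_n  = CARB_n(... CARB_1(F_0) ...)
    F_N  = F_0 + tail(F_n)
    I_SR = denormalize(out_conv(upsample(F_N)))

Each CARB ends in a *retention* gate: global average pooling reduces
the C-channel map to a per-channel descriptor, a 1x1 bottleneck of
width C/reduction (default reduction = round(sqrt(C)), i.e. a much
wider bottleneck than the classic squeeze-excitation C/16) re-weights
the channels through a sigmoid, and the gated trunk output is added to
the block input. The wide bottleneck keeps more of the channel
statistics of stained-tissue textures, whose high-frequency content is
spread across many channels rather than concentrated in a few.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor, pixel_shuffle
from .nn import Module, Conv2d

__all__ = [
    "CarnConfig",
    "CARetention",
    "CARB",
    "Upsampler",
    "CarnModel",
    "count_parameters",
    "count_flops",
]

#: Per-channel RGB means of the curated breast-cancer training set; used
#: for input normalization and added back to the network output.
DEFAULT_RGB_MEANS = (0.7204, 0.4298, 0.6397)

SUPPORTED_SCALES = (2, 3, 4, 8)


def default_reduction(channels: int) -> int:
    """The sqrt-C rule: bottleneck width C/reduction ~= sqrt(C)."""
    return int(round(math.sqrt(channels)))


@dataclass
class CarnConfig:
    """Architecture hyperparameters.

    scale           upsampling factor r, one of {2, 3, 4, 8}
    n_carb          number of attention-retention blocks (benchmark: 8)
    channels        feature width C of every 3x3 convolution (benchmark: 64)
    reduction       channel-attention divisor; None -> round(sqrt(C))
    kernel_size     spatial extent of trunk convolutions (odd)
    convs_per_block 3x3 convolutions in a CARB trunk, ReLU between them
    rgb_means       dataset channel means subtracted at input, re-added at output
    """

    scale: int = 2
    n_carb: int = 8
    channels: int = 64
    reduction: int | None = None
    kernel_size: int = 3
    convs_per_block: int = 2
    rgb_means: tuple = field(default_factory=lambda: DEFAULT_RGB_MEANS)

    def __post_init__(self):
        if self.scale not in SUPPORTED_SCALES:
            raise ValueError(f"scale must be one of {SUPPORTED_SCALES}, got {self.scale}")
        if self.n_carb < 1:
            raise ValueError("n_carb must be positive")
        if self.channels < 1:
            raise ValueError("channels must be positive")
        if self.reduction is None:
            self.reduction = default_reduction(self.channels)
        if not 1 <= self.reduction <= self.channels:
            raise ValueError(
                f"reduction must satisfy 1 <= reduction <= channels, got {self.reduction}"
            )
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        if self.convs_per_block < 1:
            raise ValueError("convs_per_block must be positive")
        self.rgb_means = tuple(float(m) for m in self.rgb_means)
        if len(self.rgb_means) != 3:
            raise ValueError("rgb_means must have three entries")

    @property
    def gate_width(self) -> int:
        """Width of the attention bottleneck (the CA-retention mid layer)."""
        return max(1, int(round(self.channels / self.reduction)))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CarnConfig":
        return cls(**d)


class CARetention(Module):
    """Channel-attention gate: pool -> 1x1 down -> ReLU -> 1x1 up -> sigmoid."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        if not 1 <= reduction <= channels:
            raise ValueError(f"reduction {reduction} outside [1, {channels}]")
        mid = max(1, int(round(channels / reduction)))
        self.down = Conv2d(channels, mid, 1, rng=rng)
        self.up = Conv2d(mid, channels, 1, rng=rng)

    def __call__(self, f: Tensor) -> Tensor:
        if not np.all(np.isfinite(f.data)):
            raise ValueError("non-finite values in attention input")
        pooled = f.mean(axis=(2, 3), keepdims=True)  # (N, C, 1, 1)
        return self.up(self.down(pooled).relu()).sigmoid()


class CARB(Module):
    """Residual block: conv trunk, channel gate, identity skip.

    out = x + gate(trunk(x)) * trunk(x); zero trunk weights make the
    block an exact identity.
    """

    def __init__(self, channels: int, reduction: int, kernel_size: int,
                 convs_per_block: int, rng: np.random.Generator):
        pad = kernel_size // 2
        self.convs = [
            Conv2d(channels, channels, kernel_size, padding=pad, rng=rng)
            for _ in range(convs_per_block)
        ]
        self.attention = CARetention(channels, reduction, rng)

    def trunk(self, x: Tensor) -> Tensor:
        h = x
        for i, conv in enumerate(self.convs):
            if i > 0:
                h = h.relu()
            h = conv(h)
        return h

    def __call__(self, x: Tensor) -> Tensor:
        if x.data.shape[1] != self.convs[0].in_channels:
            raise ValueError(
                f"expected {self.convs[0].in_channels} channels, got {x.data.shape[1]}"
            )
        t = self.trunk(x)
        return x + self.attention(t) * t


class Upsampler(Module):
    """Sub-pixel upsampling chain.

    Scales 2/4/8 use 1/2/3 groups of [conv C->4C, shuffle x2]; scale 3
    uses a single [conv C->9C, shuffle x3].
    """

    def __init__(self, scale: int, channels: int, kernel_size: int,
                 rng: np.random.Generator):
        if scale not in SUPPORTED_SCALES:
            raise ValueError(f"unsupported scale {scale}")
        pad = kernel_size // 2
        self.factors: list[int] = (
            [3] if scale == 3 else [2] * int(round(math.log2(scale)))
        )
        self.convs = [
            Conv2d(channels, channels * f * f, kernel_size, padding=pad, rng=rng)
            for f in self.factors
        ]

    def __call__(self, x: Tensor) -> Tensor:
        for conv, f in zip(self.convs, self.factors):
            x = pixel_shuffle(conv(x), f)
        return x


class CarnModel(Module):
    """The full network; parameters are created from a seeded generator."""

    def __init__(self, config: CarnConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c, k = config.channels, config.kernel_size
        pad = k // 2
        self.head = Conv2d(3, c, k, padding=pad, rng=rng)
        self.body = [
            CARB(c, config.reduction, k, config.convs_per_block, rng)
            for _ in range(config.n_carb)
        ]
        self.body_tail = Conv2d(c, c, k, padding=pad, rng=rng)
        self.upsampler = Upsampler(config.scale, c, k, rng=rng)
        self.out_conv = Conv2d(c, 3, k, padding=pad, rng=rng)
        self._means = np.asarray(config.rgb_means).reshape(1, 3, 1, 1)

    def __call__(self, x: Tensor) -> Tensor:
        """Map an (N, 3, H, W) batch in [0, 1] to (N, 3, rH, rW)."""
        if x.ndim != 4 or x.data.shape[1] != 3:
            raise ValueError(f"expected (N, 3, H, W) input, got {x.data.shape}")
        if not np.all(np.isfinite(x.data)):
            raise ValueError("non-finite values in input image")
        h = x - Tensor(self._means)
        f0 = self.head(h)
        f = f0
        for block in self.body:
            f = block(f)
        f = f0 + self.body_tail(f)
        f = self.upsampler(f)
        return self.out_conv(f) + Tensor(self._means)

    def super_resolve(self, image: np.ndarray) -> np.ndarray:
        """Upscale one HxWx3 image in [0, 1]; output clipped to [0, 1]."""
        x = Tensor(image.transpose(2, 0, 1)[None])
        y = self(x)
        return np.clip(y.data[0].transpose(1, 2, 0), 0.0, 1.0)


def count_parameters(model: CarnModel) -> int:
    """Total number of trainable scalars (deterministic in the config)."""
    return model.num_parameters()


def _conv_macs(in_c: int, out_c: int, k: int, h: int, w: int) -> int:
    return in_c * out_c * k * k * h * w


def count_flops(model: CarnModel, input_hw: tuple = (128, 128)) -> dict:
    """Convolution multiply-accumulates for one forward pass.

    Convention: 1 MAC = 1 FLOP; convolutions only (pooling, activations
    and element-wise additions are excluded); spatial size is the
    declared low-resolution input ``input_hw``. Returned as a dict so
    reports can restate the convention next to the number.
    """
    cfg = model.config
    h, w = input_hw
    c, k = cfg.channels, cfg.kernel_size
    mid = cfg.gate_width
    total = _conv_macs(3, c, k, h, w)  # head
    per_block = (
        cfg.convs_per_block * _conv_macs(c, c, k, h, w)
        + _conv_macs(c, mid, 1, 1, 1)  # gate operates on the pooled 1x1 map
        + _conv_macs(mid, c, 1, 1, 1)
    )
    total += cfg.n_carb * per_block
    total += _conv_macs(c, c, k, h, w)  # body tail
    hh, ww = h, w
    for f in ([3] if cfg.scale == 3 else [2] * int(round(math.log2(cfg.scale)))):
        total += _conv_macs(c, c * f * f, k, hh, ww)
        hh, ww = hh * f, ww * f
    total += _conv_macs(c, 3, k, hh, ww)  # output conv at HR resolution
    return {
        "flops": float(total),
        "convention": "1 MAC = 1 FLOP, convolutions only",
        "input_hw": (h, w),
    }


# ---------------------------------------------------------------------------
# Checkpoints: a single .npz archive, format version 1. Contains the JSON
# config, every parameter array, optimizer moments, RNG state and the
# update counter, so training resumes bit-exactly.

CHECKPOINT_VERSION = 1


def save_checkpoint(path, model: CarnModel, optimizer=None, rng_state: dict | None = None,
                    update: int = 0, extra: dict | None = None) -> None:
    arrays = {f"param:{k}": v for k, v in model.state_dict().items()}
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": model.config.to_dict(),
        "update": int(update),
        "rng_state": rng_state,
        "extra": extra or {},
    }
    if optimizer is not None:
        st = optimizer.state_dict()
        meta["adam_t"] = st["t"]
        for i, (m, v) in enumerate(zip(st["m"], st["v"])):
            arrays[f"adam_m:{i}"] = m
            arrays[f"adam_v:{i}"] = v
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path):
    """Return (model, meta dict). Optimizer moments stay in meta['adam']."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        model = CarnModel(CarnConfig.from_dict(meta["config"]))
        model.load_state_dict(
            {k[len("param:"):]: z[k] for k in z.files if k.startswith("param:")}
        )
        if "adam_t" in meta:
            n = len(model.parameters())
            meta["adam"] = {
                "t": meta["adam_t"],
                "m": [z[f"adam_m:{i}"] for i in range(n)],
                "v": [z[f"adam_v:{i}"] for i in range(n)],
            }
    return model, meta
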