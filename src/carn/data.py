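"""Image IO, bicubic degradation, normalization statistics, patches, tiling.

Images travel as HxWx3 float64 arrays on [0, 1]. The bicubic resampler
is Pillow's float-mode implementation: the Keys cubic kernel (a = -0.5)
with kernel-support scaling on downscale, which acts as the antialias
prefilter. The dialect matters because PSNR comparisons between SR
methods are sensitive to the degradation kernel, so it is pinned here
and used for every HR -> LR degradation in the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "ImagePatch",
    "NormStats",
    "PatchPair",
    "load_image",
    "save_image",
    "bicubic_resize",
    "compute_norm_stats",
    "apply_normalization",
    "invert_normalization",
    "make_pair",
    "extract_training_patch",
    "augment_rot90",
    "tile_image",
]

# An ImagePatch is simply an HxWx3 float array in [0, 1]; kept as a name
# for documentation purposes.
ImagePatch = np.ndarray


@dataclass(frozen=True)
class NormStats:
    """Per-channel dataset means used for input normalization."""

    mean_r: float
    mean_g: float
    mean_b: float

    def __post_init__(self):
        for m in (self.mean_r, self.mean_g, self.mean_b):
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"channel mean {m} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.mean_r, self.mean_g, self.mean_b])


@dataclass(frozen=True)
class PatchPair:
    """An aligned low/high-resolution pair; hr is exactly scale x lr."""

    lr: np.ndarray
    hr: np.ndarray
    scale: int

    def __post_init__(self):
        lh, lw = self.lr.shape[:2]
        hh, hw = self.hr.shape[:2]
        if (hh, hw) != (lh * self.scale, lw * self.scale):
            raise ValueError(
                f"hr {hh}x{hw} is not {self.scale}x the lr {lh}x{lw}"
            )


def _validate(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected HxWx3 image, got shape {img.shape}")
    if img.min() < 0.0 or img.max() > 1.0:
        raise ValueError("pixel values outside [0, 1]")
    return img


def load_image(path) -> np.ndarray:
    """Read an 8-bit RGB PNG as float64 in [0, 1] (divide by 255)."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.float64)
    return arr / 255.0


def save_image(path, img: np.ndarray) -> None:
    """Write as 8-bit RGB PNG, rounding half away from zero."""
    img = _validate(img)
    q = np.floor(img * 255.0 + 0.5).clip(0, 255).astype(np.uint8)
    Image.fromarray(q, mode="RGB").save(path, format="PNG")


def bicubic_resize(img: np.ndarray, factor) -> np.ndarray:
    """Bicubic rescale by a rational factor; output clipped to [0, 1].

    Output dimensions factor*H x factor*W must be integers.
    """
    img = _validate(img)
    f = Fraction(factor).limit_denominator(10**6)
    if f <= 0:
        raise ValueError("factor must be positive")
    h, w = img.shape[:2]
    nh, nw = h * f, w * f
    if nh.denominator != 1 or nw.denominator != 1:
        raise ValueError(
            f"factor {factor} gives non-integer output size for {h}x{w}"
        )
    nh, nw = int(nh), int(nw)
    out = np.empty((nh, nw, 3))
    for c in range(3):
        chan = Image.fromarray(img[:, :, c].astype(np.float32), mode="F")
        out[:, :, c] = np.asarray(
            chan.resize((nw, nh), Image.Resampling.BICUBIC), dtype=np.float64
        )
    return np.clip(out, 0.0, 1.0)


def compute_norm_stats(images) -> NormStats:
    """Pixel-weighted per-channel means over an iterable of images/paths."""
    total = np.zeros(3)
    count = 0
    for item in images:
        img = load_image(item) if isinstance(item, (str, Path)) else _validate(item)
        total += img.sum(axis=(0, 1))
        count += img.shape[0] * img.shape[1]
    if count == 0:
        raise ValueError("cannot compute normalization statistics of an empty set")
    m = total / count
    return NormStats(float(m[0]), float(m[1]), float(m[2]))


def apply_normalization(img: np.ndarray, stats: NormStats) -> np.ndarray:
    """Subtract per-channel means pixel-wise (result may leave [0, 1])."""
    return np.asarray(img, dtype=np.float64) - stats.as_array()


def invert_normalization(img: np.ndarray, stats: NormStats,
                         snap_grid: bool = True) -> np.ndarray:
    """Inverse of apply_normalization.

    Plain floating-point subtract-then-add can be off by one ulp, so by
    default the result is snapped back onto the 8-bit pixel grid k/255.
    Every image this pipeline reads is PNG-derived and lies exactly on
    that grid, which makes invert(apply(x)) bit-exact. Pass
    snap_grid=False for data that does not come from 8-bit images.
    """
    out = np.asarray(img, dtype=np.float64) + stats.as_array()
    if snap_grid:
        out = np.floor(out * 255.0 + 0.5) / 255.0
    return out


def make_pair(hr: np.ndarray, scale: int) -> PatchPair:
    """Degrade a whole HR image once by bicubic 1/scale."""
    hr = _validate(hr)
    h, w = hr.shape[:2]
    if h % scale or w % scale:
        raise ValueError(f"{h}x{w} not divisible by scale {scale}")
    return PatchPair(lr=bicubic_resize(hr, Fraction(1, scale)), hr=hr, scale=scale)


def lr_patch_size(scale: int, base: int = 64) -> int:
    """Training input size: 64x64, except 48x48 for the 3x task."""
    return 48 if scale == 3 else base


def extract_training_patch(pair: PatchPair, rng: np.random.Generator,
                           patch_size: int | None = None) -> PatchPair:
    """Random aligned crop: LR window of patch_size, HR window scale x it."""
    ps = patch_size if patch_size is not None else lr_patch_size(pair.scale)
    lh, lw = pair.lr.shape[:2]
    if lh < ps or lw < ps:
        raise ValueError(f"LR image {lh}x{lw} smaller than patch size {ps}")
    y = int(rng.integers(0, lh - ps + 1))
    x = int(rng.integers(0, lw - ps + 1))
    s = pair.scale
    return PatchPair(
        lr=pair.lr[y:y + ps, x:x + ps],
        hr=pair.hr[s * y:s * (y + ps), s * x:s * (x + ps)],
        scale=s,
    )


def augment_rot90(pair: PatchPair, rng: np.random.Generator) -> PatchPair:
    """Rotate both members by the same multiple of 90 degrees."""
    k = int(rng.integers(0, 4))
    if k == 0:
        return pair
    return PatchPair(
        lr=np.ascontiguousarray(np.rot90(pair.lr, k)),
        hr=np.ascontiguousarray(np.rot90(pair.hr, k)),
        scale=pair.scale,
    )


def tile_image(img: np.ndarray, tile: int) -> list[np.ndarray]:
    """Non-overlapping row-major tiles; dimensions must divide exactly."""
    img = _validate(img)
    h, w = img.shape[:2]
    if h % tile or w % tile:
        raise ValueError(f"{h}x{w} not divisible by tile size {tile}")
    return [
        img[y:y + tile, x:x + tile]
        for y in range(0, h, tile)
        for x in range(0, w, tile)
    ]
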