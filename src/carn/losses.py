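"""Differentiable training objectives.

The combined objective is a fixed linear blend of three terms,

    L = alpha * L1 + beta * MSE + gamma * (1 - SSIM),

with default weights (0.8, 0.1, 0.1): L1 drives sharp high-frequency
reconstruction, the small MSE term stabilises pixel-level accuracy, and
the SSIM term rewards local structural agreement. All terms operate on
de-normalized image-space batches (N, 3, H, W) so the SSIM dynamic
range of 1.0 is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, conv2d

__all__ = ["LossWeights", "SsimParams", "l1_loss", "mse_loss", "ssim_loss",
           "ssim_map", "combined_loss", "gaussian_window"]


@dataclass(frozen=True)
class LossWeights:
    alpha: float = 0.8   # L1
    beta: float = 0.1    # MSE
    gamma: float = 0.1   # SSIM

    def __post_init__(self):
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("loss weights must be non-negative")
        if self.alpha + self.beta + self.gamma <= 0:
            raise ValueError("at least one loss weight must be positive")


@dataclass(frozen=True)
class SsimParams:
    """Reference SSIM parameterization: 11x11 Gaussian window, sigma 1.5."""

    window_size: int = 11
    gaussian_sigma: float = 1.5
    k1: float = 0.01
    k2: float = 0.03
    dynamic_range: float = 1.0

    def __post_init__(self):
        if self.window_size < 3 or self.window_size % 2 == 0:
            raise ValueError("window_size must be an odd integer >= 3")
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("k1 and k2 must be positive")


def _check_pair(pred: Tensor, target: Tensor) -> None:
    if pred.data.shape != target.data.shape:
        raise ValueError(
            f"shape mismatch: {pred.data.shape} vs {target.data.shape}"
        )


def l1_loss(pred: Tensor, target: Tensor) -> Tensor:
    """Mean absolute difference over all samples, channels and pixels."""
    _check_pair(pred, target)
    return (pred - target).abs().mean()


def mse_loss(pred: Tensor, target: Tensor) -> Tensor:
    """Mean squared difference over all samples, channels and pixels."""
    _check_pair(pred, target)
    return (pred - target).square().mean()


def gaussian_window(size: int, sigma: float) -> np.ndarray:
    """Normalized 2-D Gaussian window (separable, truncated at size//2)."""
    r = size // 2
    g = np.exp(-0.5 * (np.arange(-r, r + 1) / sigma) ** 2)
    g /= g.sum()
    return np.outer(g, g)


def ssim_map(pred: Tensor, target: Tensor, params: SsimParams = SsimParams()) -> Tensor:
    """Local SSIM over the valid window positions of each channel.

    Windowed means/variances come from a valid (unpadded) convolution
    with the Gaussian window, applied depthwise by folding channels into
    the batch axis, so the whole map is differentiable.
    """
    _check_pair(pred, target)
    n, c, h, w = pred.data.shape
    win = params.window_size
    if win > h or win > w:
        raise ValueError(f"SSIM window {win} larger than image {h}x{w}")
    # the Gaussian window is separable: two 1-D passes
    r = win // 2
    g1 = np.exp(-0.5 * (np.arange(-r, r + 1) / params.gaussian_sigma) ** 2)
    g1 /= g1.sum()
    kern_v = Tensor(g1.reshape(1, 1, win, 1))
    kern_h = Tensor(g1.reshape(1, 1, 1, win))

    def filt(t: Tensor) -> Tensor:
        return conv2d(conv2d(t.reshape(n * c, 1, h, w), kern_v), kern_h)

    c1 = (params.k1 * params.dynamic_range) ** 2
    c2 = (params.k2 * params.dynamic_range) ** 2
    mu_x = filt(pred)
    mu_y = filt(target)
    var_x = filt(pred * pred) - mu_x * mu_x
    var_y = filt(target * target) - mu_y * mu_y
    cov = filt(pred * target) - mu_x * mu_y
    num = (2.0 * mu_x * mu_y + c1) * (2.0 * cov + c2)
    den = (mu_x * mu_x + mu_y * mu_y + c1) * (var_x + var_y + c2)
    return num / den


def ssim_loss(pred: Tensor, target: Tensor, params: SsimParams = SsimParams()) -> Tensor:
    """1 - mean local SSIM; 0 for identical images, at most 2."""
    return 1.0 - ssim_map(pred, target, params).mean()


def combined_loss(pred: Tensor, target: Tensor,
                  weights: LossWeights = LossWeights(),
                  params: SsimParams = SsimParams()) -> dict:
    """All loss components plus their weighted total, as Tensors.

    Returns {"l1", "mse", "ssim_loss", "total"}; the SSIM term is skipped
    (reported as exact 0) when gamma == 0 so pure-L1/MSE configurations
    pay no window-convolution cost.
    """
    l1 = l1_loss(pred, target)
    mse = mse_loss(pred, target)
    sl = ssim_loss(pred, target, params) if weights.gamma > 0 else Tensor(0.0)
    total = weights.alpha * l1 + weights.beta * mse + weights.gamma * sl
    return {"l1": l1, "mse": mse, "ssim_loss": sl, "total": total}
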