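"""Evaluation metrics: PSNR (dB) and the SSIM index, plus CSV reports.

Both operate on HxWx3 (or HxW) float arrays on the unit scale, with no
border cropping by default; a crop_border argument is available because
published SR protocols differ on this point.
"""

from __future__ import annotations

import csv
import math

import numpy as np
from scipy.signal import fftconvolve

from .losses import SsimParams, gaussian_window

__all__ = ["psnr", "ssim_index", "write_metrics_report"]


def _crop(img: np.ndarray, border: int) -> np.ndarray:
    if border:
        return img[border:-border, border:-border]
    return img


def psnr(pred: np.ndarray, target: np.ndarray, peak: float = 1.0,
         crop_border: int = 0) -> float:
    """10*log10(peak^2 / MSE); +inf for identical images."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    mse = np.mean((_crop(pred, crop_border) - _crop(target, crop_border)) ** 2)
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(peak * peak / mse)


def ssim_index(pred: np.ndarray, target: np.ndarray,
               params: SsimParams = SsimParams(), crop_border: int = 0) -> float:
    """Mean local SSIM over valid Gaussian-window positions.

    Channels are scored independently and averaged. Matches the
    classic parameterization (11x11 Gaussian, sigma 1.5, K=(0.01, 0.03),
    no sample-covariance correction). The theoretical range is [-1, 1];
    values are reported unclipped.
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    pred = _crop(pred, crop_border)
    target = _crop(target, crop_border)
    if pred.ndim == 2:
        pred = pred[..., None]
        target = target[..., None]
    h, w, _ = pred.shape
    if params.window_size > min(h, w):
        raise ValueError(
            f"SSIM window {params.window_size} larger than image {h}x{w}"
        )
    kern = gaussian_window(params.window_size, params.gaussian_sigma)
    c1 = (params.k1 * params.dynamic_range) ** 2
    c2 = (params.k2 * params.dynamic_range) ** 2

    def f(a):
        return fftconvolve(a, kern, mode="valid")

    vals = []
    for ch in range(pred.shape[2]):
        x, y = pred[:, :, ch], target[:, :, ch]
        mu_x, mu_y = f(x), f(y)
        var_x = f(x * x) - mu_x**2
        var_y = f(y * y) - mu_y**2
        cov = f(x * y) - mu_x * mu_y
        m = ((2 * mu_x * mu_y + c1) * (2 * cov + c2)) / (
            (mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2)
        )
        vals.append(m.mean())
    return float(np.mean(vals))


def write_metrics_report(path, rows: list[dict]) -> None:
    """Write per-image metrics as CSV (file, scale, psnr_db, ssim) + mean row."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["file", "scale", "psnr_db", "ssim"])
        for r in rows:
            writer.writerow([r["file"], r["scale"], f"{r['psnr_db']:.4f}",
                             f"{r['ssim']:.6f}"])
        if rows:
            finite = [r["psnr_db"] for r in rows if math.isfinite(r["psnr_db"])]
            mean_psnr = float(np.mean(finite)) if finite else math.inf
            mean_ssim = float(np.mean([r["ssim"] for r in rows]))
            writer.writerow(["mean", rows[0]["scale"], f"{mean_psnr:.4f}",
                             f"{mean_ssim:.6f}"])
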