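"""Seeded generator of histology-like RGB test patches.

Real stained-tissue patches have three statistical signatures the rest
of the package depends on: a narrow pink/purple color distribution
(dataset channel means near (0.72, 0.43, 0.64)), dense high-frequency
texture from honeycomb/palisade cell arrangements, and occasional large
white background regions where tissue does not cover the slide. The
generator emulates exactly these three properties with multi-octave
value noise, dark elliptical "nuclei", and a contiguous white corner
region of controllable area, so every pipeline stage is exercisable
without any real slide data. The patches are statistical stand-ins
only; they carry no diagnostic content.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates

from .builder import white_fraction as measure_white_fraction
from .data import save_image

__all__ = ["FixtureSpec", "generate_patch", "generate_dataset"]

# blended into elliptical nuclei; dark blue-purple hematoxylin tone
_NUCLEUS_COLOR = np.array([0.36, 0.20, 0.47])


@dataclass(frozen=True)
class FixtureSpec:
    size: int = 128
    n_images: int = 16
    seed: int = 0
    target_mean: tuple = (0.72, 0.43, 0.64)
    white_fraction: float = 0.0
    nucleus_density: float = 1.0   # ~1 nucleus per 20x20 px at 1.0
    texture_scale: float = 1.0

    def __post_init__(self):
        if self.size < 64:
            raise ValueError("size must be at least 64")
        if not 0.0 <= self.white_fraction < 1.0:
            raise ValueError("white_fraction must lie in [0, 1)")


def _value_noise(rng: np.random.Generator, size: int, period: float) -> np.ndarray:
    """Bilinear value noise with the given lattice period, roughly in [-1, 1]."""
    n = int(np.ceil(size / period)) + 2
    lattice = rng.uniform(-1.0, 1.0, size=(n, n))
    coords = np.arange(size) / period
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    return map_coordinates(lattice, [yy, xx], order=1, mode="nearest")


def generate_patch(spec: FixtureSpec, index: int) -> np.ndarray:
    """Deterministic HxWx3 patch in [0, 1] for (spec.seed, index)."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, index]))
    s = spec.size

    # texture: coarse-to-fine octaves plus per-pixel grain
    tex = np.zeros((s, s))
    period = s / 4.0
    amp = 1.0
    while period >= 2.0:
        tex += amp * _value_noise(rng, s, period * spec.texture_scale)
        period /= 2.0
        amp *= 0.55
    tex += 0.18 * rng.uniform(-1.0, 1.0, size=(s, s))

    # a second, coarser field decorrelates the channels a little
    hue = _value_noise(rng, s, s / 6.0)

    img = np.empty((s, s, 3))
    img[:, :, 0] = spec.target_mean[0] + 0.10 * tex + 0.03 * hue
    img[:, :, 1] = spec.target_mean[1] + 0.13 * tex - 0.04 * hue
    img[:, :, 2] = spec.target_mean[2] + 0.11 * tex + 0.05 * hue

    # dark elliptical nuclei
    n_nuclei = int(round(spec.nucleus_density * s * s / 400.0))
    for _ in range(n_nuclei):
        cy, cx = rng.uniform(0, s, size=2)
        a = rng.uniform(2.0, 5.0) * spec.texture_scale
        b = rng.uniform(2.0, 5.0) * spec.texture_scale
        theta = rng.uniform(0, np.pi)
        blend = rng.uniform(0.55, 0.85)
        r = int(np.ceil(max(a, b))) + 1
        y0, y1 = max(0, int(cy) - r), min(s, int(cy) + r + 1)
        x0, x1 = max(0, int(cx) - r), min(s, int(cx) + r + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dy, dx = yy - cy, xx - cx
        u = (dx * np.cos(theta) + dy * np.sin(theta)) / a
        v = (-dx * np.sin(theta) + dy * np.cos(theta)) / b
        mask = u * u + v * v <= 1.0
        region = img[y0:y1, x0:x1]
        region[mask] = (1.0 - blend) * region[mask] + blend * _NUCLEUS_COLOR

    # calibrate tissue channel means toward the target palette
    for _ in range(2):
        img += np.asarray(spec.target_mean) - img.mean(axis=(0, 1))
        np.clip(img, 0.01, 0.99, out=img)

    # contiguous white background region grown from a random corner
    if spec.white_fraction > 0.0:
        corner = rng.integers(0, 4)
        cy = 0.0 if corner < 2 else s - 1.0
        cx = 0.0 if corner % 2 == 0 else s - 1.0
        yy, xx = np.mgrid[0:s, 0:s]
        dist = np.hypot(yy - cy, xx - cx)
        radius = np.quantile(dist, spec.white_fraction)
        mask = dist <= radius
        img[mask] = 0.955 + 0.04 * rng.random((int(mask.sum()), 3))

    return np.clip(img, 0.0, 1.0)


def generate_dataset(spec: FixtureSpec, out_dir,
                     white_fractions=None) -> list[dict]:
    """Write n_images PNGs plus a truth table; return the truth rows.

    white_fractions optionally overrides spec.white_fraction per image
    (useful for constructing filter-test mixtures). The truth table
    (truth.tsv) records each image's measured white fraction and channel
    means so curation steps can be asserted against ground truth.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if white_fractions is not None and len(white_fractions) != spec.n_images:
        raise ValueError("white_fractions must have one entry per image")
    rows = []
    for i in range(spec.n_images):
        sp = spec if white_fractions is None else replace(
            spec, white_fraction=float(white_fractions[i])
        )
        img = generate_patch(sp, i)
        name = f"fixture_{i:04d}.png"
        save_image(out_dir / name, img)
        rows.append({
            "path": name,
            "white_fraction": measure_white_fraction(img),
            "mean_r": float(img[:, :, 0].mean()),
            "mean_g": float(img[:, :, 1].mean()),
            "mean_b": float(img[:, :, 2].mean()),
        })
    lines = ["path\twhite_fraction\tmean_r\tmean_g\tmean_b"]
    for r in rows:
        lines.append(
            f"{r['path']}\t{r['white_fraction']:.6f}\t{r['mean_r']:.6f}"
            f"\t{r['mean_g']:.6f}\t{r['mean_b']:.6f}"
        )
    (out_dir / "truth.tsv").write_text("\n".join(lines) + "\n")
    return rows
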