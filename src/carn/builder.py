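"""Dataset curation for histopathology super-resolution benchmarks.

Whole-slide patch collections contain many near-blank patches (slide
background), which carry no high-frequency tissue signal. The builder
turns a directory of extracted RGB patches into a curated benchmark in
three steps:

1. blank filtering — convert to grayscale (BT.601 luma), binarize at a
   grayscale threshold (default 224, i.e. white means gray 225-255) and
   drop patches whose white fraction exceeds 60%;
2. ranking — compute each survivor's RGB mean R_i and the pixel-weighted
   global mean R_all, rank by Euclidean distance ||R_i - R_all|| and keep
   the top k (default 1,200), maximizing inter-sample color spread;
3. split — a seeded shuffle assigns the first 1,000 to train and the
   remaining 200 to test.

The result is a TSV manifest with a JSON provenance header; rebuilding
with the same inputs, config and seed is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .data import load_image

__all__ = [
    "PatchRecord",
    "BuilderConfig",
    "white_fraction",
    "scan_directory",
    "filter_blank",
    "rank_and_select",
    "split",
    "build_manifest",
    "write_manifest",
    "read_manifest",
]

MANIFEST_COLUMNS = ("path", "split", "white_fraction",
                    "mean_r", "mean_g", "mean_b", "distance")


@dataclass
class PatchRecord:
    path: str
    white_fraction: float
    rgb_mean: tuple          # (R, G, B) means of this patch, unit scale
    n_pixels: int
    distance: float = float("nan")
    split: str = ""


@dataclass(frozen=True)
class BuilderConfig:
    gray_threshold: int = 224
    white_fraction_max: float = 0.60
    keep_top_k: int = 1200
    train_count: int = 1000
    test_count: int = 200
    patch_size: int = 1024

    def __post_init__(self):
        if not 0 <= self.gray_threshold <= 255:
            raise ValueError("gray_threshold must be on the 8-bit scale")
        if self.train_count + self.test_count != self.keep_top_k:
            raise ValueError("train_count + test_count must equal keep_top_k")


def white_fraction(img: np.ndarray, gray_threshold: int = 224) -> float:
    """Fraction of pixels whose 8-bit BT.601 gray value exceeds the threshold.

    With the default threshold 224 a pixel is white iff its rounded gray
    value lies in 225-255.
    """
    img = np.asarray(img, dtype=np.float64)
    gray = np.floor(
        255.0 * (0.299 * img[:, :, 0] + 0.587 * img[:, :, 1] + 0.114 * img[:, :, 2])
        + 0.5
    )
    return float(np.count_nonzero(gray > gray_threshold) / gray.size)


def scan_directory(directory, cfg: BuilderConfig = BuilderConfig()) -> list[PatchRecord]:
    """Measure white fraction and RGB means for every PNG in a directory."""
    directory = Path(directory)
    records = []
    for path in sorted(directory.glob("*.png")):
        img = load_image(path)
        records.append(
            PatchRecord(
                path=path.name,
                white_fraction=white_fraction(img, cfg.gray_threshold),
                rgb_mean=tuple(float(v) for v in img.mean(axis=(0, 1))),
                n_pixels=img.shape[0] * img.shape[1],
            )
        )
    return records


def filter_blank(records: list[PatchRecord],
                 cfg: BuilderConfig = BuilderConfig()) -> list[PatchRecord]:
    """Drop records strictly above the white-fraction cap; order preserved."""
    return [r for r in records if r.white_fraction <= cfg.white_fraction_max]


def rank_and_select(records: list[PatchRecord],
                    cfg: BuilderConfig = BuilderConfig()) -> list[PatchRecord]:
    """Keep the keep_top_k records farthest in RGB-mean from the global mean.

    The global mean R_all is pixel-weighted over the surviving records.
    Ties are broken lexicographically on the path so the selection is a
    pure function of its inputs.
    """
    if len(records) < cfg.keep_top_k:
        raise ValueError(
            f"only {len(records)} records survive filtering; "
            f"{cfg.keep_top_k} required"
        )
    weights = np.array([r.n_pixels for r in records], dtype=np.float64)
    means = np.array([r.rgb_mean for r in records])
    r_all = (means * weights[:, None]).sum(axis=0) / weights.sum()
    for r, m in zip(records, means):
        r.distance = float(np.linalg.norm(m - r_all))
    ranked = sorted(records, key=lambda r: (-r.distance, r.path))
    return ranked[: cfg.keep_top_k]


def split(selected: list[PatchRecord], cfg: BuilderConfig, seed: int) -> list[PatchRecord]:
    """Seeded shuffle; first train_count records become train, rest test."""
    if len(selected) != cfg.keep_top_k:
        raise ValueError(f"expected {cfg.keep_top_k} selected records")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(selected))
    out = [selected[i] for i in order]
    for i, r in enumerate(out):
        r.split = "train" if i < cfg.train_count else "test"
    return out


def build_manifest(input_dir, cfg: BuilderConfig, seed: int) -> list[PatchRecord]:
    """Run scan -> filter -> rank -> split; a pure function of its inputs."""
    records = scan_directory(input_dir, cfg)
    kept = filter_blank(records, cfg)
    selected = rank_and_select(kept, cfg)
    return split(selected, cfg, seed)


def write_manifest(path, records: list[PatchRecord], cfg: BuilderConfig,
                   seed: int, tool_version: str = "1") -> None:
    header = {"config": asdict(cfg), "seed": seed, "version": tool_version}
    lines = ["# " + json.dumps(header, sort_keys=True),
             "\t".join(MANIFEST_COLUMNS)]
    for r in records:
        lines.append("\t".join([
            r.path, r.split, f"{r.white_fraction:.6f}",
            f"{r.rgb_mean[0]:.6f}", f"{r.rgb_mean[1]:.6f}",
            f"{r.rgb_mean[2]:.6f}", f"{r.distance:.6f}",
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_manifest(path) -> tuple[list[dict], dict]:
    """Return (rows, provenance header)."""
    header: dict = {}
    rows: list[dict] = []
    columns: list[str] | None = None
    for line in Path(path).read_text().splitlines():
        if not line:
            continue
        if line.startswith("#"):
            header = json.loads(line[1:].strip())
            continue
        if columns is None:
            columns = line.split("\t")
            continue
        vals = line.split("\t")
        row = dict(zip(columns, vals))
        for key in ("white_fraction", "mean_r", "mean_g", "mean_b", "distance"):
            row[key] = float(row[key])
        rows.append(row)
    return rows, header
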