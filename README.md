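# carn

Single-image super-resolution for histopathology patches, built around a
channel-attention **retention** network: a short chain of residual
blocks whose attention bottleneck follows the √C rule
(`Reduction = round(√C)`, i.e. width 8 at 64 channels — much wider than
classic squeeze-excitation), nested residual skips inside and across
blocks, sub-pixel (pixel-shuffle) upsampling for 2/3/4/8×, and a
combined objective

```
L = α·L1 + β·MSE + γ·(1 − SSIM),   (α, β, γ) = (0.8, 0.1, 0.1).
```

The package also ships the dataset-curation pipeline that turns a
directory of 1024×1024 slide patches into a super-resolution benchmark
(blank-patch filtering at a 224 grayscale threshold, RGB-mean-distance
ranking to the top 1,200, seeded 1,000/200 split), the bicubic HR→LR
degradation and patch pipeline, PSNR/SSIM evaluation, a 128×128 tiler
for downstream classification, and a seeded generator of histology-like
synthetic patches so everything is testable without slide data.

The network, reverse-mode autodiff and ADAM are implemented in NumPy
(float64) — no deep-learning framework required. Who it is for:
researchers studying SR on stained-tissue imagery who want a small,
fully inspectable, exactly reproducible reference implementation rather
than peak throughput.

## Worked example

```python
import numpy as np
from carn import CarnConfig, CarnModel, TrainConfig, make_pair, train, evaluate
from carn.fixtures import FixtureSpec, generate_patch
from carn.train import bicubic_predictor

# 12 synthetic stained-tissue patches, deterministic in the seed
spec = FixtureSpec(size=96, n_images=12, seed=7)
images = [generate_patch(spec, i) for i in range(12)]
pairs = [make_pair(img, scale=2) for img in images]     # bicubic HR->LR

model = CarnModel(CarnConfig(scale=2, n_carb=2, channels=16), seed=1)
cfg = TrainConfig(max_updates=300, batch_size=4, patch_size=24, lr_init=1e-3)
result = train(model, pairs[:10], cfg, seed=1)
print(f"loss {result.log[0]['total']:.3f} -> {result.log[-1]['total']:.3f}")

held_out = pairs[10:]
ours = evaluate(held_out, model.super_resolve)
base = evaluate(held_out, bicubic_predictor(2))
print(f"model   {ours.mean_psnr:.2f} dB / SSIM {ours.mean_ssim:.3f}")
print(f"bicubic {base.mean_psnr:.2f} dB / SSIM {base.mean_ssim:.3f}")
```

Output:

```
loss 0.308 -> 0.021
model   33.74 dB / SSIM 0.902
bicubic 33.72 dB / SSIM 0.897
```

The combined loss falls by ~15× within 300 updates, and even this
300-update toy run edges past bicubic on held-out fixtures; the
package's desk-scale benchmark (2,000 updates, 32 fixtures —
`carn.benchmark.desk_benchmark`) widens the gap to ≈ +2.6 dB. On real
slide-derived benchmarks the full configuration is
`CarnConfig(scale=2)` — 8 blocks, 64 channels, reduction 8 — trained
with the 1e-4 halving schedule over seeds {1, 7, 11, 18, 1011}.

The same workflow from the shell:

```
carn fixtures --n 32 --size 256 --seed 7 --out patches/
carn build --input patches/ --output bench/ --top-k 24 --train 20 --test 4 --seed 1
carn train --manifest bench/manifest.tsv --data-dir patches/ --scale 2 \
           --seed 1 --updates 2000 --patch-size 32 --out model.npz
carn eval  --checkpoint model.npz --manifest bench/manifest.tsv \
           --data-dir patches/ --out report.csv
carn sr    --checkpoint model.npz --input patches/fixture_0000.png --output sr.png
carn report --scale 2 --n-carb 8 --channels 64   # parameter/FLOP totals
```

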