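# Methods

## Problem

Single-image super-resolution (SISR) reconstructs a high-resolution
(HR) image from one low-resolution (LR) input. For digitized pathology
slides this matters economically: scanning whole slides at the highest
objective is slow and expensive, so upscaling patches scanned at a
lower level is an attractive substitute — provided the reconstruction
preserves the high-frequency cellular texture a diagnostician relies
on. Stained tissue differs from natural photographs in two ways that
drive every design choice here: its high-frequency content (honeycomb /
palisade cell arrangements) is dense and spatially uniform rather than
concentrated at object boundaries, and its color gamut is narrow
(pink/purple hematoxylin–eosin palette).

## Model

The network maps an LR RGB patch to an `r×` upscaled patch
(`r ∈ {2, 3, 4, 8}`):

```
F0  = Conv3x3( I_LR − μ )                      # head; μ = dataset RGB means
Fm  = CARB_m(F_{m-1}),  m = 1..N               # chained residual blocks
F   = F0 + Conv3x3(F_N)                        # long skip
I_SR = Conv3x3( Upsample(F) ) + μ
```

**CARB (channel-attention retention block).** Each block is

```
t    = Conv3x3(ReLU(Conv3x3(x)))               # trunk
g    = σ( W_up · ReLU( W_down · avgpool(t) ) ) # per-channel gate in (0,1)
out  = x + g ⊙ t
```

`avgpool` is a global spatial mean per channel; `W_down`/`W_up` are 1×1
convolutions with bottleneck width `C / Reduction`. The distinguishing
choice versus classic squeeze-excitation attention is the **√C rule**:
`Reduction = round(√C)` (8 for C = 64), giving a bottleneck of width
√C ≈ 8 rather than the usual C/16 = 4. The wider bottleneck discards
less channel information, which suits tissue images where useful
high-frequency signal is spread over many channels. Zeroing the trunk
makes each block an exact identity (tested at bit level), so depth can
only add information — the usual residual argument.

**Upsampler.** Sub-pixel (pixel-shuffle) stages: scales 2/4/8 use 1/2/3
groups of `[Conv C→4C, shuffle ×2]`; scale 3 uses one
`[Conv C→9C, shuffle ×3]`. The shuffle index map
`out[c, r·h+dy, r·w+dx] = in[c·r²+dy·r+dx, h, w]` is tested against an
explicit enumeration.

**Normalization.** Per-channel dataset means are subtracted at the
input and added back after the output convolution, so the body learns a
residual around the dataset mean. Defaults are the curated training-set
means `(0.7204, 0.4298, 0.6397)`; they are a config field and should be
recomputed (`compute_norm_stats`) for other datasets.

## Objective

`L = α·L1 + β·MSE + γ·(1 − SSIM)` with defaults
`(α, β, γ) = (0.8, 0.1, 0.1)`. L1 dominates (sharper textures than pure
MSE), the MSE term damps metric fluctuation, and the SSIM term rewards
local structural agreement. SSIM uses the reference parameterization —
11×11 Gaussian window, σ = 1.5, K = (0.01, 0.03), dynamic range 1.0, no
sample-covariance correction — computed over valid window positions;
the implementation agrees with `skimage.metrics.structural_similarity`
(gaussian_weights=True, use_sample_covariance=False) to better than
1e-6 and is fully differentiable (the Gaussian filter is expressed as
two separable 1-D convolutions inside the autodiff graph). The loss is
evaluated on de-normalized image-space outputs so the SSIM dynamic
range is meaningful. Evaluation metrics are RGB PSNR (peak 1.0,
identical images reported as +∞) and the same SSIM, with no border
cropping by default and a `crop_border` option because published SR
protocols differ on this point.

## Numerical core

No deep-learning framework is used. `carn.autodiff` is a compact
reverse-mode automatic-differentiation engine over float64 NumPy
arrays (broadcasting arithmetic, ReLU/sigmoid, axis reductions,
reshape/transpose, stride-1 zero-padded convolution via im2col matmul,
pixel shuffle). The convolution input-gradient is computed as a full
correlation with the flipped kernel — a second im2col matmul — rather
than a scatter loop. Every analytic gradient is verified against
central finite differences (relative error < 1e-7 in the tests). ADAM
uses β₁ = 0.9, β₂ = 0.999, ε = 1e-8 with bias correction; the step
count, moment estimates and data-RNG state are checkpointed (single
`.npz` archive, format version 1), making resume bit-exact — asserted
by comparing an interrupted-and-resumed loss trajectory to an
uninterrupted one.

## Training protocol

- Learning rate `lr(t) = 1e-4 · 0.5^⌊t / 2·10⁵⌋` (initial 1e-4, halved
  every 2×10⁵ minibatch updates).
- LR crops of 64×64 (48×48 at scale 3), aligned HR windows at exactly
  `scale×` the LR coordinates; random 90° rotation augmentation only
  (no flips). Degradation is bicubic, applied once per whole image at
  dataset build; crops are taken from the pre-degraded LR so no
  per-crop resampling bias enters.
- Batch size 16 by default (a config field; not a claimed-faithful
  value), replicate seeds {1, 7, 11, 18, 1011} with across-seed
  averaging of reported PSNR/SSIM (`evaluate_replicates`).

**Bicubic dialect.** Pillow's float-mode resampler: Keys kernel
a = −0.5 with kernel-support scaling on downscale (the antialias
prefilter). Pinned deliberately — PSNR comparisons between SR methods
are sensitive to the degradation dialect.

## Dataset construction

From a directory of extracted 1024×1024 RGB patches (slide parsing and
coordinate sampling are out of scope):

1. **Blank filter** — BT.601 luma `0.299R + 0.587G + 0.114B`, rounded
   to the 8-bit grid; a pixel is white iff gray ≥ 225 (threshold 224);
   patches with *strictly more than* 60% white pixels are removed.
2. **Distance ranking** — per-patch RGB mean `R_i`, pixel-weighted
   global mean `R_all` over filter survivors, Euclidean distance
   `‖R_i − R_all‖₂`, descending sort with lexicographic-path
   tie-breaks, keep the top 1,200. This maximizes inter-sample color
   spread so a model must attend to a wider range of appearances.
3. **Split** — seeded shuffle, 1,000 train / 200 test. The partition
   method is this package's choice (recorded in the manifest header);
   the counts are the benchmark's definition.

The pipeline is a pure function of (directory listing, config, seed);
rebuilding yields a byte-identical manifest. For downstream
classification experiments, `tile_image` cuts each 1024×1024 patch into
64 non-overlapping 128×128 tiles (row-major; labels pass through from
file naming).

## Synthetic fixtures

`carn.fixtures` generates seeded histology-like patches: multi-octave
bilinear value noise plus per-pixel grain mapped onto the pink/purple
palette (channel means calibrated to (0.72, 0.43, 0.64) by iterated
mean-shift with clipping), dark elliptical nuclei, and an optional
contiguous white corner region whose area is set by a distance-quantile
so the measured white fraction lands within ±0.02 of the request. What
they emulate: the stain palette, dense high-frequency texture
(Laplacian energy floor asserted in tests), and blank-background
statistics — enough to exercise degradation, curation, training and
evaluation. What they do not emulate: real nuclear morphology, stain
variation between laboratories, scanner optics, or any diagnostic
signal. Passing tests on fixtures therefore validate the machinery and
the ordering of methods, not clinical image quality.

## Desk-scale benchmark

`carn.benchmark.desk_benchmark` runs the whole pipeline at a size one
CPU finishes in minutes: 2 blocks, 16 channels, 32 training and 8
held-out 96×96 fixtures at scale 2, batch 8, 32×32 LR crops, 2,000 ADAM
updates at a constant 1e-3 (the production 1e-4 halving schedule is
tuned to runs two orders of magnitude longer than a desk run). The
check is the *ordering*: the trained model must beat bicubic
upscaling on held-out fixtures (observed ≈ +2.6 dB at seed 1) with a
non-increasing 500-update moving average of the training loss.
Absolute PSNR values on fixtures are not comparable to slide-derived
benchmarks.

## Parameter and FLOP accounting

`count_parameters` is exact (affine in the number of blocks; constant
per-block increment — both asserted). `count_flops` counts convolution
multiply-accumulates only, 1 MAC = 1 FLOP, at a declared LR input size
(default 128×128), and returns the convention string with the number.
The benchmark configuration (8 blocks, 64 channels, scale 2) totals
0.788 M parameters and 12.8 G MAC-FLOPs under these conventions,
reported alongside the literature reference values 1.389 M / 11.300 G
for the same nominal architecture: the block-internal composition of
the reference is not fully specified and its counting conventions are
unstated, so parity of the affine structure — not of the absolute
totals — is the claim, and `FLOPs(N=12) − FLOPs(N=8) =
FLOPs(N=8) − FLOPs(N=4)` holds exactly. The trunk depth is exposed as
`convs_per_block` for users who want to chase a particular budget.

## Numerical and design choices

- Same (zero) padding everywhere; feature maps keep H×W until the
  shuffle stages.
- Kaiming fan-in initialization for convolution weights, zero biases,
  all from one seeded generator per model.
- Attention bottleneck width `max(1, round(C / Reduction))`; `FeatDS`
  and `FeatUS` are 1×1 convolutions (the descriptor is spatially 1×1,
  so larger kernels would be meaningless).
- The gate multiplies the trunk output channel-wise *before* the
  block's residual addition.
- 8-bit PNG ↔ [0, 1]: divide by 255 on read; round half away from zero
  on write.
- `invert_normalization` snaps to the k/255 grid by default: plain
  subtract-then-add can be one ulp off, and every image this pipeline
  reads lies on that grid, so snapping makes invert∘apply bit-exact
  (pass `snap_grid=False` for non-8-bit data).
- L1's subgradient at zero is taken as 0.
- PSNR of identical images is reported as +∞ (excluded from means).
- Degenerate inputs raise `ValueError` early: non-finite pixels,
  channel mismatches, SSIM windows larger than the image, empty
  manifests or training sets, indivisible tile/scale dimensions,
  ranking shortfalls.

## Known limitations

- CPU-only float64 training: practical for the desk-scale benchmark and
  small studies, not for benchmark-scale runs (8 blocks, 64 channels,
  10⁵–10⁶ updates).
- Bicubic-only degradation, as in the benchmark definition; no noise,
  blur or compression models.
- The absolute parameter/FLOP totals depend on the documented
  conventions; only magnitudes and the affine structure are comparable
  across implementations.
- Fixture results bound implementation correctness, not performance on
  real slides.
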