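"""Training loop, learning-rate schedule and the evaluation harness.

The optimizer protocol: ADAM (beta1=0.9, beta2=0.999, eps=1e-8) on the
combined L1/MSE/SSIM objective, with a step-halving schedule

    lr(t) = lr_init * 0.5 ** floor(t / lr_halve_every),

lr_init = 1e-4 halved every 2x10^5 minibatch updates by default. Each
update draws a fresh batch of aligned LR/HR crops (random 90-degree
rotation augmentation) from pre-degraded whole-image pairs. Replicate
runs over the seed list {1, 7, 11, 18, 1011} are averaged for reported
metrics. All randomness flows through one seeded generator whose state
is checkpointed, so an interrupted run resumes bit-exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .data import (PatchPair, augment_rot90, bicubic_resize,
                   extract_training_patch, lr_patch_size)
from .losses import LossWeights, SsimParams, combined_loss
from .metrics import psnr, ssim_index
from .model import CarnModel, save_checkpoint, load_checkpoint
from .nn import Adam

__all__ = ["TrainConfig", "TrainResult", "EvalReport", "lr_schedule", "train",
           "evaluate", "bicubic_predictor", "evaluate_replicates"]

DEFAULT_SEEDS = (1, 7, 11, 18, 1011)


@dataclass
class TrainConfig:
    lr_init: float = 1e-4
    lr_halve_every: int = 200_000
    batch_size: int = 16
    max_updates: int = 1000
    seeds: tuple = DEFAULT_SEEDS
    loss_weights: LossWeights = field(default_factory=LossWeights)
    ssim_params: SsimParams = field(default_factory=SsimParams)
    patch_size: int | None = None   # None -> 64 (48 at scale 3)
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self):
        if self.lr_init <= 0:
            raise ValueError("lr_init must be positive")
        if self.lr_halve_every <= 0:
            raise ValueError("lr_halve_every must be positive")


def lr_schedule(update_index: int, cfg: TrainConfig) -> float:
    """Piecewise-constant halving schedule."""
    return cfg.lr_init * 0.5 ** (update_index // cfg.lr_halve_every)


@dataclass
class TrainResult:
    model: CarnModel
    log: list
    optimizer: Adam
    rng: np.random.Generator
    updates: int

    def save(self, path) -> None:
        save_checkpoint(path, self.model, self.optimizer,
                        rng_state=self.rng.bit_generator.state,
                        update=self.updates)


def _sample_batch(pairs: list[PatchPair], cfg: TrainConfig,
                  rng: np.random.Generator) -> tuple[Tensor, Tensor]:
    scale = pairs[0].scale
    ps = cfg.patch_size if cfg.patch_size is not None else lr_patch_size(scale)
    lr_stack, hr_stack = [], []
    for _ in range(cfg.batch_size):
        pair = pairs[int(rng.integers(len(pairs)))]
        crop = augment_rot90(extract_training_patch(pair, rng, ps), rng)
        lr_stack.append(crop.lr.transpose(2, 0, 1))
        hr_stack.append(crop.hr.transpose(2, 0, 1))
    return Tensor(np.stack(lr_stack)), Tensor(np.stack(hr_stack))


def train(model: CarnModel, pairs: list[PatchPair], cfg: TrainConfig,
          seed: int = 1, log_path=None, resume_meta: dict | None = None,
          start_update: int = 0) -> TrainResult:
    """Optimize `model` in place; returns the log and resumable state.

    Pass `resume_meta` (the meta dict from load_checkpoint) together with
    the same model object to continue an interrupted run bit-exactly.
    """
    if not pairs:
        raise ValueError("empty training set")
    optimizer = Adam(model.parameters(), cfg.adam_beta1, cfg.adam_beta2,
                     cfg.adam_eps)
    rng = np.random.default_rng(seed)
    if resume_meta is not None:
        if "adam" in resume_meta:
            optimizer.load_state_dict(resume_meta["adam"])
        if resume_meta.get("rng_state"):
            rng.bit_generator.state = resume_meta["rng_state"]
        start_update = int(resume_meta.get("update", start_update))

    log: list[dict] = []
    log_fh = open(log_path, "a") if log_path else None
    try:
        for t in range(start_update, cfg.max_updates):
            lr = lr_schedule(t, cfg)
            x, y = _sample_batch(pairs, cfg, rng)
            pred = model(x)
            losses = combined_loss(pred, y, cfg.loss_weights, cfg.ssim_params)
            model.zero_grad()
            losses["total"].backward()
            optimizer.step(lr)
            entry = {
                "update": t,
                "lr": lr,
                "l1": losses["l1"].item(),
                "mse": losses["mse"].item(),
                "ssim_loss": losses["ssim_loss"].item(),
                "total": losses["total"].item(),
            }
            log.append(entry)
            if log_fh:
                log_fh.write(json.dumps(entry) + "\n")
    finally:
        if log_fh:
            log_fh.close()
    return TrainResult(model=model, log=log, optimizer=optimizer, rng=rng,
                       updates=cfg.max_updates)


@dataclass
class EvalReport:
    rows: list
    mean_psnr: float
    mean_ssim: float


def evaluate(pairs: list[PatchPair], predictor, names=None,
             crop_border: int = 0,
             ssim_params: SsimParams = SsimParams()) -> EvalReport:
    """Score a predictor (lr HxWx3 -> sr HxWx3) against HR ground truth."""
    rows = []
    for i, pair in enumerate(pairs):
        sr = predictor(pair.lr)
        rows.append({
            "file": names[i] if names else f"image_{i:04d}",
            "scale": pair.scale,
            "psnr_db": psnr(sr, pair.hr, crop_border=crop_border),
            "ssim": ssim_index(sr, pair.hr, ssim_params, crop_border=crop_border),
        })
    finite = [r["psnr_db"] for r in rows if math.isfinite(r["psnr_db"])]
    return EvalReport(
        rows=rows,
        mean_psnr=float(np.mean(finite)) if finite else math.inf,
        mean_ssim=float(np.mean([r["ssim"] for r in rows])),
    )


def bicubic_predictor(scale: int):
    """The classical baseline: plain bicubic upscaling of the LR input."""
    return lambda lr: bicubic_resize(lr, scale)


def evaluate_replicates(make_model, train_pairs: list[PatchPair],
                        test_pairs: list[PatchPair], cfg: TrainConfig,
                        seeds=None, crop_border: int = 0) -> dict:
    """Train once per seed, evaluate each run, average across seeds.

    make_model(seed) must build a freshly initialized model. Returns
    per-seed mean PSNR/SSIM plus the across-seed means that serve as the
    reported objective metrics.
    """
    seeds = list(seeds if seeds is not None else cfg.seeds)
    per_seed = []
    for seed in seeds:
        model = make_model(seed)
        train(model, train_pairs, cfg, seed=seed)
        report = evaluate(test_pairs, model.super_resolve, crop_border=crop_border)
        per_seed.append({"seed": seed, "psnr": report.mean_psnr,
                         "ssim": report.mean_ssim})
    return {
        "per_seed": per_seed,
        "mean_psnr": float(np.mean([r["psnr"] for r in per_seed])),
        "mean_ssim": float(np.mean([r["ssim"] for r in per_seed])),
    }


def load_for_resume(path) -> tuple[CarnModel, dict]:
    """Convenience wrapper pairing load_checkpoint with train(resume_meta=...)."""
    return load_checkpoint(path)
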