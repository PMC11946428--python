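"""Training loop: Adam with step-decay learning rate, deep supervision with
a periodically decayed auxiliary weight, foreground-oversampled patch
sampling, and 3:1 train/validation splitting.

Schedules
---------
* learning rate: lr0 * 0.8^floor(epoch / 30) (20% reduction every 30 epochs)
* auxiliary deep-supervision weight: alpha = 0.4, multiplied by 0.8 once per
  decay period

Stage semantics: the liver stage trains on label >= 1 over the whole
preprocessed volume; the tumor stage trains on label == 2 with inputs
cropped to the (ground-truth) liver bounding box plus margin and masked to
the liver region, so tumor features come from liver tissue only.
"""
from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .grids import Volume
from .losses import LossConfig, deep_supervision_total, decay_ds_alpha, \
    logits_loss
from .network import NetworkConfig, build_network
from .nn import Adam, Tensor
from .cascade import sliding_window_predict, liver_roi
from .grids import Mask

__all__ = ["TrainConfig", "lr_at_epoch", "make_splits", "sample_patches",
           "train_stage", "save_checkpoint", "load_checkpoint"]


@dataclass
class TrainConfig:
    lr0: float = 1e-4
    lr_decay: float = 0.8
    lr_decay_period: int = 30
    epochs: int = 10
    steps_per_epoch: int = 30
    batch_size: int = 1
    patch_size: tuple = (64, 64, 32)
    foreground_oversample: float = 0.5
    loss_name: str = "hybrid1"
    split_ratio: str = "3:1"
    roi_margin: int = 10
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)

    def __post_init__(self):
        if self.lr0 <= 0:
            raise ValueError("initial learning rate must be positive")
        if not 0 < self.lr_decay <= 1:
            raise ValueError("lr decay factor must lie in (0, 1]")
        a, b = (int(v) for v in self.split_ratio.split(":"))
        self.train_fraction = a / (a + b)


def lr_at_epoch(epoch: int, config: TrainConfig) -> float:
    """Step-decay learning rate, piecewise constant over decay periods."""
    if epoch < 0:
        raise ValueError("epoch must be non-negative")
    return config.lr0 * config.lr_decay ** (epoch // config.lr_decay_period)


def make_splits(case_ids, ratio: str = "3:1", seed: int = 0):
    """Deterministic shuffled split; |train| = round(fraction * n)."""
    ids = list(case_ids)
    if len(ids) < 4:
        raise ValueError("need at least 4 cases to split")
    a, b = (int(v) for v in ratio.split(":"))
    frac = a / (a + b)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = round(frac * len(ids))
    train = [ids[i] for i in order[:n_train]]
    val = [ids[i] for i in order[n_train:]]
    return train, val


def sample_patches(image: np.ndarray, target: np.ndarray, patch_size,
                   n_patches: int, oversample_fraction: float = 0.5,
                   seed: int = 0, warn=None):
    """Random training patches, a configured fraction centered on foreground.

    Returns a list of (input_patch, target_patch, corner) with the corner in
    padded-volume coordinates.  Deterministic per seed.  If oversampling is
    requested but the case has no foreground, falls back to uniform
    sampling (optionally reporting through ``warn``).
    """
    rng = np.random.default_rng(seed)
    pads = [(0, max(0, p - s)) for s, p in zip(image.shape, patch_size)]
    if any(p[1] for p in pads):
        image = np.pad(image, pads)
        target = np.pad(target, pads)
    fg = np.argwhere(target > 0)
    if oversample_fraction > 0 and len(fg) == 0:
        if warn is not None:
            warn("no foreground voxels; falling back to uniform sampling")
        oversample_fraction = 0.0
    out = []
    max_corner = [s - p for s, p in zip(image.shape, patch_size)]
    for _ in range(n_patches):
        if rng.random() < oversample_fraction:
            # jittered placement: the chosen foreground voxel lands at a
            # uniform position inside the patch, not at its center, so the
            # network cannot key on patch-relative location
            center = fg[rng.integers(len(fg))]
            offs = [int(rng.integers(0, p)) for p in patch_size]
            corner = [int(np.clip(c - o, 0, m))
                      for c, o, m in zip(center, offs, max_corner)]
        else:
            corner = [int(rng.integers(0, m + 1)) for m in max_corner]
        sl = tuple(slice(c, c + p) for c, p in zip(corner, patch_size))
        out.append((image[sl], target[sl], tuple(corner)))
    return out


def _stage_arrays(case, stage: str, roi_margin: int):
    """(input grid, binary target) for one preprocessed case and stage."""
    image, labels = case
    grid = image.voxels if isinstance(image, Volume) else np.asarray(image)
    if stage == "liver":
        return grid.astype(np.float32), (labels >= 1).astype(np.uint8)
    if stage != "tumor":
        raise ValueError("stage must be 'liver' or 'tumor'")
    liver = Mask((labels >= 1).astype(np.uint8), (1, 1, 1))
    if liver.count() == 0:
        return grid.astype(np.float32), (labels == 2).astype(np.uint8)
    lo, hi = liver_roi(liver, roi_margin)
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    from .cascade import mask_normalize_roi
    masked = mask_normalize_roi(grid[sl], labels[sl] >= 1)
    return masked, (labels[sl] == 2).astype(np.uint8)


def _validation_dice(model, cases, stage, config) -> float:
    scores = []
    for case in cases:
        img, tgt = _stage_arrays(case, stage, config.roi_margin)
        prob = sliding_window_predict(model, img, config.patch_size)
        pred = prob >= 0.5
        denom = pred.sum() + tgt.sum()
        scores.append(1.0 if denom == 0 else 2.0 * (pred & (tgt > 0)).sum()
                      / denom)
    return float(np.mean(scores)) if scores else float("nan")


def train_stage(model, cases, config: TrainConfig, stage: str = "liver",
                val_cases=None, log=None):
    """Train one cascade stage; returns (best state dict, history dict).

    ``cases`` are (Volume[normalized], label grid) pairs in preprocessed
    space.  History tracks per-epoch mean total loss, the deep-supervision
    weight, the learning rate, and validation Dice; the returned weights are
    those of the best validation epoch (training loss when no validation
    cases are given).  Aborts on non-finite loss.
    """
    loss_fn = logits_loss(config.loss_name, config.loss)
    opt = Adam(model.parameters(), lr=config.lr0)
    rng = np.random.default_rng(config.seed)
    ds_alpha = config.loss.ds_alpha0
    history = {"epoch": [], "loss": [], "ds_alpha": [], "lr": [],
               "val_dice": []}
    arrays = [_stage_arrays(c, stage, config.roi_margin) for c in cases]
    best = (-np.inf, None)
    for epoch in range(config.epochs):
        opt.lr = lr_at_epoch(epoch, config)
        if epoch > 0 and epoch % config.loss.ds_decay_period_epochs == 0:
            ds_alpha = decay_ds_alpha(ds_alpha, config.loss.ds_decay)
        model.train()
        epoch_losses = []
        for step in range(config.steps_per_epoch):
            idx = int(rng.integers(len(arrays)))
            img, tgt = arrays[idx]
            (xi, yi, _), = sample_patches(
                img, tgt, config.patch_size, 1,
                config.foreground_oversample,
                seed=int(rng.integers(2 ** 31)))
            x = Tensor(xi[None, None])
            y = yi[None, None].astype(np.float32)
            outs = model(x)
            losses = [loss_fn(o, y) for o in outs]
            total = deep_supervision_total(losses, ds_alpha)
            if not np.isfinite(total.item()):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} step {step}; "
                    "training diverged")
            opt.zero_grad()
            total.backward()
            opt.step()
            epoch_losses.append(total.item())
        val = _validation_dice(model, val_cases, stage, config) \
            if val_cases else None
        score = val if val is not None else -float(np.mean(epoch_losses))
        if score > best[0]:
            best = (score, {k: v.copy() for k, v in
                            model.state_dict().items()})
        history["epoch"].append(epoch)
        history["loss"].append(float(np.mean(epoch_losses)))
        history["ds_alpha"].append(ds_alpha)
        history["lr"].append(opt.lr)
        history["val_dice"].append(val)
        if log:
            log(f"epoch {epoch}: loss {history['loss'][-1]:.4f} "
                f"lr {opt.lr:.2e} ds_alpha {ds_alpha:.4f} "
                f"val_dice {val if val is not None else float('nan'):.4f}")
    if best[1] is not None:
        model.load_state_dict(best[1])
    return best[1] or model.state_dict(), history


def save_checkpoint(path, model, net_config: NetworkConfig,
                    train_config: TrainConfig | None = None,
                    extras: dict | None = None):
    meta = {"network": net_config.to_dict()}
    if train_config is not None:
        d = asdict(train_config)
        d.pop("loss", None)
        d.pop("train_fraction", None)
        meta["train"] = d
    if extras:
        meta["extras"] = extras
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    np.savez(path, __meta__=json.dumps(meta),
             **{f"w::{k}": v for k, v in model.state_dict().items()})


def load_checkpoint(path):
    """Returns (model, meta dict); the model is rebuilt from the stored
    config and weights."""
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        state = {k[3:]: z[k] for k in z.files if k.startswith("w::")}
    cfg = NetworkConfig.from_dict(meta["network"])
    deploy = cfg.deploy
    cfg.deploy = False
    model = build_network(cfg)
    if deploy:
        from .reparam import convert_to_deploy
        convert_to_deploy(model)
    model.load_state_dict(state)
    return model, meta
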