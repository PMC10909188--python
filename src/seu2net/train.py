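"""Training and evaluation procedure.

Optimization follows the published recipe: momentum SGD with the
Nesterov flag, batch size 4, a cosine-annealed learning rate starting at
0.0015 and decaying to 0 over a 5400-iteration cycle (with warm restarts
when training runs longer than one cycle), 9000 iterations in total and
a checkpoint every 900.  The objective is the 0.7 cross-entropy + 0.3
Dice mixture applied, by default, to the fused map and all six side
outputs (deep supervision); evaluation always uses the fused output:
per-pixel argmax over the class channels (ties resolve to background,
the first index), confusion counts accumulated globally over the split,
and the four metrics reported in percent.

A reduced-width smoke setup (8 phantom slices at 96x96, 200 iterations)
exercises the full loop at CPU scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .losses import LOSS_MODES, LossWeights, supervised_loss
from .metrics import ConfusionCounts, MetricReport, accumulate, compute_report
from .model import U2Net, save_checkpoint, small_config
from .nn import SGD, softmax
from .phantom import PhantomSpec, lesion_mask, make_phantom_volume
from .preprocess import WindowSpec, slice_to_png

__all__ = [
    "ScheduleConfig",
    "TrainConfig",
    "cosine_lr",
    "SliceDataset",
    "train",
    "evaluate",
    "evaluate_predictions",
    "predict",
    "checkpoint_iterations",
    "smoke_setup",
]


@dataclass(frozen=True)
class ScheduleConfig:
    """Cosine annealing: eta(t) = eta_min + (eta_max - eta_min)/2 *
    (1 + cos(pi * t_cycle / period))."""

    eta_max: float = 0.0015
    eta_min: float = 0.0
    period: int = 5400
    restart: bool = True

    def __post_init__(self):
        if self.eta_min > self.eta_max:
            raise ValueError("eta_min must not exceed eta_max")
        if self.period < 1:
            raise ValueError("period must be >= 1")


def cosine_lr(t: int, cfg: ScheduleConfig) -> float:
    """Learning rate at iteration ``t`` (restarting or clamped cycles)."""
    if t < 0:
        raise ValueError("iteration must be non-negative")
    tc = t % cfg.period if cfg.restart else min(t, cfg.period)
    return cfg.eta_min + 0.5 * (cfg.eta_max - cfg.eta_min) * (
        1.0 + math.cos(math.pi * tc / cfg.period))


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 4
    total_iters: int = 9000
    checkpoint_every: int = 900
    momentum: float = 0.9
    nesterov: bool = True
    weight_decay: float = 0.0
    loss: str = "mixture"
    deep_supervision: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.loss not in LOSS_MODES:
            raise ValueError(f"loss must be one of {sorted(LOSS_MODES)}")
        if self.batch_size < 1 or self.total_iters < 1 or self.checkpoint_every < 1:
            raise ValueError("batch size, iterations and checkpoint cadence must be positive")


def checkpoint_iterations(cfg: TrainConfig) -> list[int]:
    """1-based iteration numbers at which checkpoints are written."""
    return list(range(cfg.checkpoint_every, cfg.total_iters + 1, cfg.checkpoint_every))


class SliceDataset:
    """In-memory set of (image, mask) training pairs.

    Images are (3, H, W) float32 in [0, 1] (grayscale replicated to
    three channels); masks are (H, W) uint8 in {0, 1}.
    """

    def __init__(self, images: np.ndarray, masks: np.ndarray):
        images = np.asarray(images, dtype=np.float32)
        masks = np.asarray(masks)
        if images.ndim != 4 or images.shape[1] != 3:
            raise ValueError("images must be (N, 3, H, W)")
        if masks.shape != (images.shape[0],) + images.shape[2:]:
            raise ValueError("masks must be (N, H, W) matching the images")
        self.images = images
        self.masks = masks.astype(np.uint8)

    def __len__(self) -> int:
        return self.images.shape[0]

    @staticmethod
    def _img_from_u8(gray: np.ndarray) -> np.ndarray:
        x = gray.astype(np.float32) / 255.0
        return np.repeat(x[None], 3, axis=0)

    @classmethod
    def from_pairs(cls, pairs: list[tuple[Path, Path]]) -> "SliceDataset":
        """Load image/mask PNG pairs from disk."""
        imgs, masks = [], []
        for img_path, mask_path in pairs:
            gray = np.asarray(Image.open(img_path).convert("L"))
            mask = np.asarray(Image.open(mask_path).convert("L"))
            imgs.append(cls._img_from_u8(gray))
            masks.append((mask > 127).astype(np.uint8))
        return cls(np.stack(imgs), np.stack(masks))

    @classmethod
    def from_manifest(cls, manifest_path) -> "SliceDataset":
        manifest_path = Path(manifest_path)
        manifest = json.loads(manifest_path.read_text())
        base = manifest_path.parent
        pairs = [(base / p["image"], base / p["mask"]) for p in manifest["pairs"]]
        return cls.from_pairs(pairs)

    @classmethod
    def from_phantom(cls, spec: PhantomSpec, n_best: int | None = None,
                     window: WindowSpec | None = None) -> "SliceDataset":
        """Build directly from a phantom volume; ``n_best`` keeps the
        slices with the most lesion pixels (all slices otherwise)."""
        window = window or WindowSpec()
        rec = make_phantom_volume(spec)
        fg = lesion_mask(rec.labels, spec.label_convention)
        areas = fg.sum(axis=(0, 1))
        order = np.argsort(-areas, kind="stable")
        keep = sorted(order[:n_best]) if n_best else list(range(rec.n_slices))
        imgs = [cls._img_from_u8(slice_to_png(rec.axial_image(k), window)) for k in keep]
        masks = [fg[:, :, k].astype(np.uint8) for k in keep]
        return cls(np.stack(imgs), np.stack(masks))


def _as_probs(outputs):
    fused, sides = outputs
    return softmax(fused, axis=1), [softmax(s, axis=1) for s in sides]


def train(model: U2Net, dataset: SliceDataset, tcfg: TrainConfig,
          scfg: ScheduleConfig | None = None, out_dir=None,
          val_dataset: SliceDataset | None = None,
          weights: LossWeights | None = None) -> list[dict]:
    """Run the optimization loop; returns the per-iteration log.

    Log entries carry iteration (1-based), learning rate and training
    loss; checkpoint entries additionally carry the checkpoint path and,
    when a validation set is given, its metric report.
    """
    if len(dataset) == 0:
        raise ValueError("training dataset is empty")
    scfg = scfg or ScheduleConfig()
    weights = weights or LossWeights()
    rng = np.random.default_rng(tcfg.seed)
    opt = SGD(model.parameters(), lr=scfg.eta_max, momentum=tcfg.momentum,
              nesterov=tcfg.nesterov, weight_decay=tcfg.weight_decay)
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    model.train()
    log: list[dict] = []
    order = np.array([], dtype=np.int64)
    for t in range(tcfg.total_iters):
        while order.size < tcfg.batch_size:
            order = np.concatenate([order, rng.permutation(len(dataset))])
        idx, order = order[: tcfg.batch_size], order[tcfg.batch_size :]
        x = dataset.images[idx]
        y = dataset.masks[idx].astype(np.int64)
        outputs = model(x)
        if not np.isfinite(outputs[0].data).all():
            raise RuntimeError(
                f"training diverged at iteration {t + 1}: non-finite network output")
        loss = supervised_loss(_as_probs(outputs), y, weights, mode=tcfg.loss,
                               fused_only=not tcfg.deep_supervision)
        loss_val = loss.item()
        if not math.isfinite(loss_val):
            raise RuntimeError(
                f"training diverged at iteration {t + 1}: loss = {loss_val}")
        opt.zero_grad()
        loss.backward()
        opt.lr = cosine_lr(t, scfg)
        opt.step()
        entry = {"iter": t + 1, "lr": opt.lr, "loss": loss_val}
        if (t + 1) % tcfg.checkpoint_every == 0 and out_dir is not None:
            ckpt = out_dir / f"checkpoint_{t + 1:06d}.npz"
            save_checkpoint(model, ckpt, meta={"iter": t + 1, "loss": loss_val})
            entry["checkpoint"] = str(ckpt)
            if val_dataset is not None:
                entry["val_metrics"] = evaluate(model, val_dataset).in_percent()
                model.train()
        log.append(entry)
    if out_dir is not None:
        with open(out_dir / "train_log.jsonl", "w") as fh:
            for entry in log:
                fh.write(json.dumps(entry) + "\n")
    return log


def predict_masks(model: U2Net, images: np.ndarray, batch_size: int = 4) -> np.ndarray:
    """Per-pixel argmax of the fused output; ties resolve to class 0."""
    model.eval()
    preds = []
    for i in range(0, images.shape[0], batch_size):
        fused, _ = model(images[i : i + batch_size])
        preds.append(np.argmax(fused.data, axis=1).astype(np.uint8))
    return np.concatenate(preds)


def evaluate_predictions(preds: np.ndarray, truths: np.ndarray) -> MetricReport:
    counts = ConfusionCounts()
    for p, t in zip(preds, truths):
        accumulate(p, t, counts)
    return compute_report(counts)


def evaluate(model: U2Net, dataset: SliceDataset, batch_size: int = 4) -> MetricReport:
    """Globally accumulated metrics of the fused prediction on a split."""
    if len(dataset) == 0:
        raise ValueError("evaluation dataset is empty")
    preds = predict_masks(model, dataset.images, batch_size)
    return evaluate_predictions(preds, dataset.masks)


def predict(model: U2Net, image_paths, out_dir) -> list[Path]:
    """Segment PNG images from disk; writes binary {0, 255} mask files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for path in map(Path, image_paths):
        gray = np.asarray(Image.open(path).convert("L"))
        x = SliceDataset._img_from_u8(gray)[None]
        mask = predict_masks(model, x)[0] * 255
        out_path = out_dir / f"{path.stem}_pred.png"
        Image.fromarray(mask.astype(np.uint8), mode="L").save(out_path)
        written.append(out_path)
    return written


def smoke_setup(seed: int = 0) -> tuple[U2Net, SliceDataset, TrainConfig, ScheduleConfig]:
    """CPU-scale end-to-end setup: reduced-width network and the eight
    96x96 phantom slices richest in lesion, 200 iterations."""
    spec = PhantomSpec(n_slices=24, height=96, width=96, n_lesions=3, seed=seed)
    dataset = SliceDataset.from_phantom(spec, n_best=8)
    model = U2Net(small_config("seu2net"), seed=seed)
    tcfg = TrainConfig(batch_size=4, total_iters=200, checkpoint_every=100, seed=seed)
    scfg = ScheduleConfig()
    return model, dataset, tcfg, scfg
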