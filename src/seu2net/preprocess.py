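"""CT volume -> 2-D PNG training pairs.

The pipeline mirrors the standard preparation of labelled abdominal CT
for 2-D segmentation: find the axial slice range that actually contains
labelled anatomy, reduce the label volume to a binary lesion mask
(three-class challenge data keeps only the tumor class; binary clinical
data keeps any positive label), window the HU image to 8 bits and write
image/mask PNG pairs plus a JSON manifest.  Volumes are partitioned into
train/val/test at the volume level in an 8:1:1 ratio so adjacent slices
of one patient can never straddle a split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from PIL import Image

from .volume import VolumeRecord

__all__ = [
    "WindowSpec",
    "SplitAssignment",
    "liver_slice_range",
    "binarize_labels",
    "slice_to_png",
    "export_volume",
    "split_dataset",
]

CONVENTIONS = ("pufh", "lits")


@dataclass(frozen=True)
class WindowSpec:
    """Display window: HU values clipped to [hu_min, hu_max] then scaled
    linearly to 0..255.  Default [-200, 300] covers soft tissue."""

    hu_min: float = -200.0
    hu_max: float = 300.0

    def __post_init__(self):
        if not self.hu_min < self.hu_max:
            raise ValueError(f"degenerate window [{self.hu_min}, {self.hu_max}]")


def _check_convention(convention: str) -> None:
    if convention not in CONVENTIONS:
        raise ValueError(f"convention must be one of {CONVENTIONS}, got {convention!r}")


def liver_slice_range(labels: np.ndarray, convention: str) -> tuple[int, int]:
    """Inclusive (z_first, z_last) range of axial slices with relevant labels.

    Both conventions look for any positive label: for three-class data
    that is liver-or-tumor (the liver extent), for binary data it is the
    lesion extent itself.
    """
    _check_convention(convention)
    labels = np.asarray(labels)
    present = (labels > 0).any(axis=(0, 1))
    idx = np.flatnonzero(present)
    if idx.size == 0:
        raise ValueError("label volume contains no labelled voxels: empty slice range")
    return int(idx[0]), int(idx[-1])


def binarize_labels(label_slice: np.ndarray, convention: str) -> np.ndarray:
    """Reduce one label slice to the binary lesion mask.

    lits: tumor label 2 -> 1, background/liver {0, 1} -> 0.
    pufh: any positive label -> 1.
    """
    _check_convention(convention)
    label_slice = np.asarray(label_slice)
    values = np.unique(label_slice)
    allowed = {0, 1, 2} if convention == "lits" else {0, 1}
    bad = set(int(v) for v in values) - allowed
    if bad:
        raise ValueError(f"unexpected label value(s) {sorted(bad)} for convention {convention!r}")
    if convention == "lits":
        return (label_slice == 2).astype(np.uint8)
    return (label_slice > 0).astype(np.uint8)


def slice_to_png(image_slice: np.ndarray, w: WindowSpec,
                 size: int | None = None) -> np.ndarray:
    """Window an HU slice to an 8-bit array (round-half-up), optionally
    resized to size x size (bilinear; masks are resized elsewhere with
    nearest neighbour)."""
    image_slice = np.asarray(image_slice, dtype=np.float64)
    if not np.all(np.isfinite(image_slice)):
        raise ValueError("image slice contains non-finite values")
    scaled = (np.clip(image_slice, w.hu_min, w.hu_max) - w.hu_min) * (
        255.0 / (w.hu_max - w.hu_min))
    out = np.floor(scaled + 0.5).astype(np.uint8)
    if size is not None and out.shape != (size, size):
        out = np.asarray(Image.fromarray(out, mode="L").resize((size, size), Image.BILINEAR))
    return out


def export_volume(rec: VolumeRecord, convention: str, out_dir,
                  w: WindowSpec | None = None, size: int | None = 512) -> dict:
    """Write one image/mask PNG pair per slice in the labelled range."""
    _check_convention(convention)
    w = w or WindowSpec()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    z0, z1 = liver_slice_range(rec.labels, convention)
    pairs = []
    for k in range(z0, z1 + 1):
        img8 = slice_to_png(rec.axial_image(k), w, size)
        mask = binarize_labels(rec.axial_labels(k), convention)
        if size is not None and mask.shape != (size, size):
            mask = np.asarray(
                Image.fromarray(mask, mode="L").resize((size, size), Image.NEAREST))
        img_name = f"{rec.id}_{k:04d}.png"
        mask_name = f"{rec.id}_{k:04d}_mask.png"
        Image.fromarray(img8, mode="L").save(out_dir / img_name)
        Image.fromarray((mask * 255).astype(np.uint8), mode="L").save(out_dir / mask_name)
        pairs.append({"volume": rec.id, "slice": k, "image": img_name, "mask": mask_name})
    manifest = {
        "volume": rec.id,
        "convention": convention,
        "window": asdict(w),
        "size": size,
        "slice_range": [z0, z1],
        "pairs": pairs,
    }
    (out_dir / f"{rec.id}_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


@dataclass(frozen=True)
class SplitAssignment:
    """Volume-level train/val/test partition."""

    assignment: dict[str, str]
    ratios: tuple[int, int, int]
    seed: int

    def ids(self, split: str) -> list[str]:
        return sorted(k for k, v in self.assignment.items() if v == split)


def split_dataset(ids, ratios: tuple[int, int, int] = (8, 1, 1),
                  seed: int = 0) -> SplitAssignment:
    """Shuffled volume-level partition.

    Validation and test receive ``floor(n * r / sum(r))`` volumes each;
    the remainder goes to train.  Deterministic under the seed.
    """
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate volume ids")
    n_parts = sum(1 for r in ratios if r > 0)
    if len(ids) < n_parts:
        raise ValueError(f"need at least {n_parts} volumes for ratios {ratios}")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    total = sum(ratios)
    n_val = len(ids) * ratios[1] // total
    n_test = len(ids) * ratios[2] // total
    assignment: dict[str, str] = {}
    for vid in order[: len(order) - n_val - n_test]:
        assignment[vid] = "train"
    for vid in order[len(order) - n_val - n_test : len(order) - n_test]:
        assignment[vid] = "val"
    for vid in order[len(order) - n_test :]:
        assignment[vid] = "test"
    return SplitAssignment(assignment=assignment, ratios=tuple(ratios), seed=seed)
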