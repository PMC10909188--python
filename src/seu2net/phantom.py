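"""Synthetic CT phantoms for liver lesion segmentation.

The generator emulates the statistical structure of contrast abdominal
CT around the liver: a large bright ellipsoidal "liver" (soft-tissue HU
around +60) on an air-like background (-1000 HU), enclosing one or more
darker spherical "lesions" (around 0 HU, mimicking cysts/hypodense
tumors), with per-voxel tissue texture and additive Gaussian noise.
Label volumes follow either the binary convention (lesion = 1) or the
three-class challenge convention (liver = 1, lesion = 2).

Everything is driven by a :class:`PhantomSpec` and a seed; an identical
spec produces bit-identical integer volumes.  Lesion spheres are placed
entirely inside the liver ellipsoid and pairwise disjoint, so lesion
count equals the number of connected foreground components.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from PIL import Image

from .volume import VolumeRecord, write_nifti  # noqa: F401  (re-exported)

__all__ = ["PhantomSpec", "make_phantom_volume", "make_slice_dataset", "write_nifti"]

LABEL_CONVENTIONS = ("pufh_binary", "lits_three_class")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic CT generator.

    Geometry is in voxel units, intensities in HU.  ``liver_center`` and
    ``liver_axes`` are (row, column, slice) triples; ``None`` picks the
    volume center and axes covering ~80% of the in-plane extent.
    """

    n_slices: int = 24
    height: int = 96
    width: int = 96
    liver_center: tuple[float, float, float] | None = None
    liver_axes: tuple[float, float, float] | None = None
    n_lesions: int = 3
    lesion_radius_range: tuple[float, float] = (3.0, 6.0)
    liver_intensity_mean: float = 60.0
    liver_intensity_sd: float = 10.0
    lesion_intensity_mean: float = 0.0
    lesion_intensity_sd: float = 15.0
    background_intensity: float = -1000.0
    noise_sd: float = 5.0
    label_convention: str = "lits_three_class"
    spacing: tuple[float, float, float] = (0.7, 0.7, 5.0)
    seed: int = 0

    def __post_init__(self):
        if self.label_convention not in LABEL_CONVENTIONS:
            raise ValueError(
                f"label_convention must be one of {LABEL_CONVENTIONS}, got {self.label_convention!r}")
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be non-negative")
        lo, hi = self.lesion_radius_range
        if not 0 < lo <= hi:
            raise ValueError("lesion_radius_range must satisfy 0 < lo <= hi")

    def resolved_geometry(self) -> tuple[np.ndarray, np.ndarray]:
        center = np.asarray(
            self.liver_center
            if self.liver_center is not None
            else (self.height / 2.0, self.width / 2.0, self.n_slices / 2.0)
        )
        axes = np.asarray(
            self.liver_axes
            if self.liver_axes is not None
            else (0.42 * self.height, 0.36 * self.width, 0.42 * self.n_slices)
        )
        return center, axes


def _validate_geometry(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    center, axes = spec.resolved_geometry()
    extent = np.asarray([spec.height, spec.width, spec.n_slices])
    if np.any(axes <= 0):
        raise ValueError("liver axes must be positive")
    if np.any(center - axes < -0.5) or np.any(center + axes > extent - 0.5):
        raise ValueError(
            f"liver ellipsoid (center {tuple(center)}, axes {tuple(axes)}) does not fit "
            f"inside the {tuple(extent)} volume")
    if spec.n_lesions and spec.lesion_radius_range[1] >= axes.min():
        raise ValueError(
            f"maximum lesion radius {spec.lesion_radius_range[1]} must be smaller than "
            f"the smallest liver axis {axes.min()}")
    return center, axes


def _place_lesions(spec: PhantomSpec, center: np.ndarray, axes: np.ndarray,
                   rng: np.random.Generator) -> list[tuple[np.ndarray, float]]:
    """Rejection-sample disjoint lesion spheres strictly inside the liver."""
    placed: list[tuple[np.ndarray, float]] = []
    lo, hi = spec.lesion_radius_range
    for _ in range(spec.n_lesions):
        for attempt in range(20000):
            r = float(rng.uniform(lo, hi))
            # whole sphere inside the ellipsoid: normalized center distance
            # bounded by 1 - r / min(axes)
            margin = 1.0 - r / float(axes.min())
            u = rng.uniform(-1.0, 1.0, size=3)
            if np.sum(u * u) > 1.0:
                continue
            c = center + u * axes * margin
            if np.sum(((c - center) / axes) ** 2) >= margin ** 2:
                continue
            if all(np.linalg.norm(c - pc) > r + pr + 2.0 for pc, pr in placed):
                placed.append((c, r))
                break
        else:
            raise ValueError(
                f"could not place {spec.n_lesions} disjoint lesions of radius "
                f"{spec.lesion_radius_range} inside liver axes {tuple(axes)}; "
                f"shrink the lesions or enlarge the liver")
    return placed


def make_phantom_volume(spec: PhantomSpec) -> VolumeRecord:
    """Generate the paired image/label volume described by ``spec``."""
    center, axes = _validate_geometry(spec)
    rng = np.random.default_rng(spec.seed)
    rr, cc, zz = np.meshgrid(
        np.arange(spec.height, dtype=np.float64),
        np.arange(spec.width, dtype=np.float64),
        np.arange(spec.n_slices, dtype=np.float64),
        indexing="ij",
    )
    liver = (((rr - center[0]) / axes[0]) ** 2
             + ((cc - center[1]) / axes[1]) ** 2
             + ((zz - center[2]) / axes[2]) ** 2) <= 1.0
    lesions = np.zeros_like(liver)
    for c, r in _place_lesions(spec, center, axes, rng):
        lesions |= ((rr - c[0]) ** 2 + (cc - c[1]) ** 2 + (zz - c[2]) ** 2) <= r * r

    image = np.full(liver.shape, spec.background_intensity, dtype=np.float64)
    image[liver] = rng.normal(spec.liver_intensity_mean, spec.liver_intensity_sd,
                              int(liver.sum()))
    image[lesions] = rng.normal(spec.lesion_intensity_mean, spec.lesion_intensity_sd,
                                int(lesions.sum()))
    image += rng.normal(0.0, spec.noise_sd, image.shape)
    image = np.clip(np.rint(image), -1024, 3071).astype(np.int16)

    labels = np.zeros(liver.shape, dtype=np.uint8)
    if spec.label_convention == "lits_three_class":
        labels[liver] = 1
        labels[lesions] = 2
    else:
        labels[lesions] = 1
    return VolumeRecord(image=image, labels=labels, spacing=spec.spacing,
                        id=f"phantom-{spec.seed}")


def lesion_mask(labels: np.ndarray, convention: str) -> np.ndarray:
    """Boolean lesion-foreground mask under either label convention."""
    if convention == "lits_three_class":
        return labels == 2
    if convention == "pufh_binary":
        return labels == 1
    raise ValueError(f"unknown label convention {convention!r}")


def make_slice_dataset(spec: PhantomSpec, out_dir,
                       window: tuple[float, float] = (-200.0, 300.0)) -> dict:
    """Write one 8-bit grayscale image PNG and one binary (0/255) lesion
    mask PNG per axial slice; returns (and writes) the manifest."""
    from .preprocess import WindowSpec, slice_to_png  # local import: no cycle at module load

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rec = make_phantom_volume(spec)
    w = WindowSpec(*window)
    fg = lesion_mask(rec.labels, spec.label_convention)
    pairs = []
    for k in range(rec.n_slices):
        img8 = slice_to_png(rec.axial_image(k), w, size=None)
        mask8 = (fg[:, :, k].astype(np.uint8)) * 255
        img_name, mask_name = f"slice_{k:04d}.png", f"slice_{k:04d}_mask.png"
        Image.fromarray(img8, mode="L").save(out_dir / img_name)
        Image.fromarray(mask8, mode="L").save(out_dir / mask_name)
        pairs.append({"slice": k, "image": img_name, "mask": mask_name,
                      "lesion_pixels": int(fg[:, :, k].sum())})
    manifest = {"spec": asdict(spec), "window": list(window), "pairs": pairs}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
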