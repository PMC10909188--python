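"""Labelled 3-D CT volumes and their NIfTI serialization.

A :class:`VolumeRecord` carries a CT image (Hounsfield units), its
integer label volume, voxel spacing and the NIfTI affine.  Arrays are
indexed (row, column, slice); axial slices are taken along the last
axis.  Serialization writes a pair of NIfTI-1 files, ``<base>.nii.gz``
for the image and ``<base>.seg.nii.gz`` for the labels, via nibabel.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VolumeRecord", "write_nifti", "read_nifti"]


@dataclass
class VolumeRecord:
    image: np.ndarray                 # (H, W, Z), HU
    labels: np.ndarray                # (H, W, Z), integer classes
    spacing: tuple[float, float, float]
    affine: np.ndarray = None
    id: str = "volume"

    def __post_init__(self):
        self.image = np.asarray(self.image)
        self.labels = np.asarray(self.labels)
        if self.image.shape != self.labels.shape:
            raise ValueError(
                f"image {self.image.shape} and labels {self.labels.shape} must be congruent")
        if self.image.ndim != 3:
            raise ValueError("volumes are 3-D (rows, columns, slices)")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])

    @property
    def n_slices(self) -> int:
        return self.image.shape[2]

    def axial_image(self, k: int) -> np.ndarray:
        return self.image[:, :, k]

    def axial_labels(self, k: int) -> np.ndarray:
        return self.labels[:, :, k]


def _paths(base) -> tuple[Path, Path]:
    base = Path(base)
    name = base.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
            break
    return base.with_name(name + ".nii.gz"), base.with_name(name + ".seg.nii.gz")


def write_nifti(rec: VolumeRecord, base) -> tuple[Path, Path]:
    """Write image and label volumes next to each other; returns the paths."""
    img_path, seg_path = _paths(base)
    img = nib.Nifti1Image(rec.image.astype(np.int16), rec.affine)
    seg = nib.Nifti1Image(rec.labels.astype(np.uint8), rec.affine)
    for ni in (img, seg):
        ni.header.set_zooms(rec.spacing)
    nib.save(img, img_path)
    nib.save(seg, seg_path)
    return img_path, seg_path


def read_nifti(base) -> VolumeRecord:
    img_path, seg_path = _paths(base)
    img = nib.load(img_path)
    seg = nib.load(seg_path)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeRecord(
        image=np.asarray(img.dataobj).astype(np.int16),
        labels=np.asarray(seg.dataobj).astype(np.uint8),
        spacing=spacing,
        affine=np.asarray(img.affine),
        id=img_path.name[: -len(".nii.gz")],
    )
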