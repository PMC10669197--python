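"""Shared 3D image containers and NIfTI I/O.

The pipeline only relies on per-axis voxel spacing (mm) and an origin
offset; full affine orientation handling is out of scope.  Voxel indices
are 0-based and a voxel's physical position is ``origin + index * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["Volume3D", "BinaryMask", "load_volume", "save_volume", "save_mask", "load_mask"]


@dataclass
class Volume3D:
    """Scalar 3D image with anisotropic voxel spacing in mm."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must have 3 components")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_to_mm(self, index) -> np.ndarray:
        """Physical position (mm) of voxel center(s); accepts (3,) or (N, 3)."""
        return np.asarray(self.origin) + np.asarray(index, dtype=float) * np.asarray(self.spacing)

    def mm_to_voxel(self, point) -> np.ndarray:
        """Nearest voxel index for physical point(s) in mm."""
        idx = (np.asarray(point, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)
        return np.rint(idx).astype(int)

    def contains_index(self, index) -> bool:
        index = np.asarray(index)
        return bool(np.all(index >= 0) and np.all(index < np.asarray(self.shape)))


@dataclass
class BinaryMask(Volume3D):
    """Boolean 3D grid sharing the geometry of its source volume."""

    values: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        super().__post_init__()

    @classmethod
    def like(cls, volume: Volume3D, values: np.ndarray) -> "BinaryMask":
        values = np.asarray(values)
        if values.shape != volume.shape:
            raise ValueError(
                f"mask shape {values.shape} does not match volume shape {volume.shape}"
            )
        return cls(values=values, spacing=volume.spacing, origin=volume.origin)


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def save_volume(volume: Volume3D, path) -> None:
    img = nib.Nifti1Image(np.asarray(volume.values, dtype=np.float32), _affine(volume.spacing, volume.origin))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def save_mask(mask: BinaryMask, path) -> None:
    img = nib.Nifti1Image(mask.values.astype(np.uint8), _affine(mask.spacing, mask.origin))
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def _load(path):
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return data, tuple(float(z) for z in zooms), origin


def load_volume(path) -> Volume3D:
    data, spacing, origin = _load(path)
    return Volume3D(values=np.asarray(data, dtype=float), spacing=spacing, origin=origin)


def load_mask(path) -> BinaryMask:
    data, spacing, origin = _load(path)
    return BinaryMask(values=data > 0, spacing=spacing, origin=origin)
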