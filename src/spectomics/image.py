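"""Voxel-grid containers shared by the simulator, segmentation and feature code.

Conventions: world coordinates are millimetres; array axes are (x, y, z) with
0-based indices; a voxel's world position is its centre,
``origin + index * spacing``.  The NIfTI affine is the diagonal spacing matrix
plus the origin translation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VoxelImage", "Mask", "read_nifti", "write_nifti"]


def _as_triplet(v) -> tuple[float, float, float]:
    if np.isscalar(v):
        return (float(v),) * 3
    t = tuple(float(x) for x in v)
    if len(t) != 3:
        raise ValueError(f"expected scalar or length-3 spacing/origin, got {v!r}")
    return t


@dataclass
class VoxelImage:
    """A 3D scalar field (activity concentration in kBq/ml, or SUV)."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    unit: str = "kBq/ml"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        self.spacing = _as_triplet(self.spacing)
        self.origin = _as_triplet(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def is_isotropic(self) -> bool:
        return len(set(self.spacing)) == 1

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def coordinate_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates (mm) of every voxel centre, one grid per axis."""
        axes = [o + s * np.arange(n) for o, s, n in zip(self.origin, self.spacing, self.shape)]
        return tuple(np.meshgrid(*axes, indexing="ij"))

    def world_to_index(self, point_mm) -> tuple[int, int, int]:
        """Index of the voxel whose centre is nearest to ``point_mm``."""
        idx = [int(round((p - o) / s)) for p, o, s in zip(point_mm, self.origin, self.spacing)]
        if any(i < 0 or i >= n for i, n in zip(idx, self.shape)):
            raise IndexError(f"point {tuple(point_mm)} mm falls outside the grid")
        return tuple(idx)

    def like(self, values: np.ndarray, unit: str | None = None) -> "VoxelImage":
        return VoxelImage(values, self.spacing, self.origin, unit or self.unit)


@dataclass
class Mask:
    """A boolean VOI on the same grid as its source image."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError("mask must be a 3D array")
        self.spacing = _as_triplet(self.spacing)
        self.origin = _as_triplet(self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    @property
    def volume_ml(self) -> float:
        return self.voxel_count * float(np.prod(self.spacing)) / 1000.0

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def same_grid_as(self, image: VoxelImage) -> bool:
        return (self.shape == image.shape
                and np.allclose(self.spacing, image.spacing)
                and np.allclose(self.origin, image.origin))


def write_nifti(obj: VoxelImage | Mask, path: str | Path, sidecar: dict | None = None) -> Path:
    """Write an image (float32) or mask (uint8) with its affine; optionally a
    JSON sidecar recording provenance (geometry, activities, seed, model)."""
    path = Path(path)
    if isinstance(obj, Mask):
        data = obj.values.astype(np.uint8)
    else:
        data = obj.values.astype(np.float32)
    nib.save(nib.Nifti1Image(data, obj.affine), path)
    if sidecar is not None:
        side = path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" \
            else path.with_suffix(".json")
        side.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def read_nifti(path: str | Path, unit: str = "SUV") -> VoxelImage:
    img = nib.load(str(path))
    aff = img.affine
    spacing = tuple(float(x) for x in np.abs(np.diag(aff)[:3]))
    origin = tuple(float(x) for x in aff[:3, 3])
    return VoxelImage(np.asarray(img.dataobj, dtype=np.float64), spacing, origin, unit)


def read_nifti_mask(path: str | Path) -> Mask:
    img = nib.load(str(path))
    aff = img.affine
    spacing = tuple(float(x) for x in np.abs(np.diag(aff)[:3]))
    origin = tuple(float(x) for x in aff[:3, 3])
    return Mask(np.asarray(img.dataobj) > 0, spacing, origin)
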