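"""VOI definition: rasterised spheres for the volume-dependency series and
threshold-based segmentation of the Revolver inserts.

Two threshold rules are provided.  ``adaptive_background`` thresholds at
``factor x`` the mean SUV of a background region (guideline method, factor
2.5); ``percent_max`` thresholds at ``factor x`` the maximum SUV inside a
search region (40% SUVmax).  Either way the VOI is the 26-connected
component of the supra-threshold set that contains the seed point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import VoxelImage, Mask

__all__ = [
    "SegmentationParams", "VOISeries", "rasterize_sphere",
    "spherical_voi_series", "measure_background", "segment",
    "EmptySegmentationError",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


class EmptySegmentationError(RuntimeError):
    """The threshold exceeds every voxel in the image/search region."""


@dataclass(frozen=True)
class SegmentationParams:
    method: str  # "adaptive_background" | "percent_max"
    factor: float
    background_region: Mask | None = None
    search_region: Mask | None = None

    def __post_init__(self):
        if self.method not in ("adaptive_background", "percent_max"):
            raise ValueError(f"unknown segmentation method {self.method!r}")
        if self.factor <= 0:
            raise ValueError("factor must be positive")
        if self.method == "percent_max" and not self.factor < 1:
            raise ValueError("percent_max factor must lie in (0, 1)")
        if self.method == "adaptive_background" and self.background_region is None:
            raise ValueError("adaptive_background requires a background region")


@dataclass
class VOISeries:
    """Ordered (diameter, mask) pairs sharing one centre."""

    center: tuple[float, float, float]
    diameters: list[float]
    masks: list[Mask]

    def __post_init__(self):
        if len(self.diameters) != len(self.masks):
            raise ValueError("diameters and masks differ in length")
        if any(b <= a for a, b in zip(self.diameters, self.diameters[1:])):
            raise ValueError("diameters must be strictly increasing")

    def __len__(self) -> int:
        return len(self.masks)

    def __iter__(self):
        return iter(zip(self.diameters, self.masks))

    @property
    def volumes_ml(self) -> list[float]:
        return [m.volume_ml for m in self.masks]


def rasterize_sphere(center, diameter: float, grid: VoxelImage) -> Mask:
    """Voxel-centre-inclusion sphere: a voxel belongs to the mask iff its
    centre lies within ``diameter/2`` of ``center`` (world mm)."""
    radius = diameter / 2.0
    for c, o, s, n in zip(center, grid.origin, grid.spacing, grid.shape):
        if c - radius < o - s / 2.0 or c + radius > o + (n - 0.5) * s:
            raise ValueError(
                f"sphere of diameter {diameter} mm at {tuple(center)} exceeds the grid")
    x, y, z = grid.coordinate_grids()
    d2 = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
    return Mask(d2 <= radius * radius, grid.spacing, grid.origin)


def spherical_voi_series(center, grid: VoxelImage, d_min: float = 10.0,
                         d_max: float = 122.0, step: float = 4.0,
                         interior: Mask | None = None) -> VOISeries:
    """The expanding sphere series (defaults: 10-122 mm in 4 mm steps, 29
    VOIs).  If ``interior`` is given (the phantom volume), every sphere must
    stay inside it; the error names the largest admissible diameter."""
    diameters = [d_min + step * k for k in range(int(round((d_max - d_min) / step)) + 1)]
    masks = []
    for d in diameters:
        m = rasterize_sphere(center, d, grid)
        if interior is not None and not interior.values[m.values].all():
            admissible = [dd for dd, mm in zip(diameters, masks)]
            raise ValueError(
                f"sphere of diameter {d} mm crosses the phantom boundary; "
                f"largest admissible diameter is "
                f"{max(admissible) if admissible else 'none'} mm")
        masks.append(m)
    return VOISeries(tuple(center), diameters, masks)


def measure_background(image: VoxelImage, region: Mask) -> float:
    """Mean SUV over a background region."""
    if not region.same_grid_as(image):
        raise ValueError("background region is not on the image grid")
    if region.voxel_count == 0:
        raise ValueError("background region is empty")
    return float(image.values[region.values].mean())


def segment(image: VoxelImage, params: SegmentationParams, seed_point) -> Mask:
    """Threshold the image and keep the 26-connected supra-threshold
    component containing ``seed_point`` (world mm)."""
    if params.method == "adaptive_background":
        threshold = params.factor * measure_background(image, params.background_region)
    else:
        if params.search_region is not None:
            region_max = float(image.values[params.search_region.values].max())
        else:
            region_max = float(image.values.max())
        if region_max <= image.values.min():
            raise ValueError("percent_max needs a non-constant image")
        threshold = params.factor * region_max

    above = image.values >= threshold
    if not above.any():
        raise EmptySegmentationError(
            f"threshold {threshold:.4g} exceeds the image maximum "
            f"{image.values.max():.4g}")
    labels, _ = ndimage.label(above, structure=_CONN26)
    seed_idx = image.world_to_index(seed_point)
    seed_label = labels[seed_idx]
    if seed_label == 0:
        raise EmptySegmentationError(
            f"seed point {tuple(seed_point)} is below threshold {threshold:.4g}")
    return Mask(labels == seed_label, image.spacing, image.origin)
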