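"""Morphological features of a VOI mask.

Surface area comes from a marching-cubes mesh of the binary mask (voxel-face
area for a single-voxel mask, where no mesh exists).  Sphericity is
``pi^(1/3) (6V)^(2/3) / A`` (1 for a perfect sphere, (pi/6)^(1/3) ~ 0.806 for
a cube); compacity is ``V / (sqrt(pi) A^(3/2))`` (dimensionless; 1/(6 pi) for
a sphere).  V in mm^3 and A in mm^2 except the Volume feature, reported in ml.
"""

from __future__ import annotations

import numpy as np
from skimage import measure

from ..image import Mask

__all__ = ["shape_features", "surface_area_mm2"]


def surface_area_mm2(mask: Mask) -> float:
    if mask.voxel_count == 0:
        raise ValueError("empty mask")
    if mask.voxel_count == 1:
        sx, sy, sz = mask.spacing
        return 2.0 * (sx * sy + sy * sz + sz * sx)
    padded = np.pad(mask.values, 1).astype(np.float64)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=mask.spacing)
    return float(measure.mesh_surface_area(verts, faces))


def shape_features(mask: Mask) -> tuple[dict[str, float], set[str]]:
    volume_mm3 = mask.voxel_count * float(np.prod(mask.spacing))
    area = surface_area_mm2(mask)
    out = {
        "Volume": volume_mm3 / 1000.0,
        "Surface area": area,
        "Sphericity": float(np.pi ** (1 / 3) * (6.0 * volume_mm3) ** (2 / 3) / area),
        "Compacity": float(volume_mm3 / (np.sqrt(np.pi) * area ** 1.5)),
    }
    return out, set()
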