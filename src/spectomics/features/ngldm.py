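"""Neighbourhood grey-level difference matrix (NGLDM) features.

For each in-mask voxel with at least one in-mask 26-neighbour, the absolute
difference between its level and the mean level of those neighbours is
accumulated per grey level; coarseness, contrast and busyness follow the
Amadasun-King definitions.  Voxels outside the mask never enter a
neighbourhood average.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["ngldm_features", "COARSENESS_CAP"]

#: Reported value of coarseness when the summed differences vanish (perfectly
#: uniform region); mirrors the large-value cap used by common engines.
COARSENESS_CAP = 1e6

_KERNEL = np.ones((3, 3, 3))
_KERNEL[1, 1, 1] = 0.0


def ngldm_features(levels: np.ndarray, mask: np.ndarray, n_levels: int = 64,
                   ) -> tuple[dict[str, float], set[str]]:
    m = mask.astype(np.float64)
    neigh_n = ndimage.convolve(m, _KERNEL, mode="constant", cval=0.0)
    neigh_sum = ndimage.convolve(levels * m, _KERNEL, mode="constant", cval=0.0)
    valid = mask & (neigh_n > 0)
    if not valid.any():
        raise ValueError("no voxel has an in-mask neighbour")
    lv = levels[valid]
    diff = np.abs(lv - neigh_sum[valid] / neigh_n[valid])

    n_i = np.bincount(lv, minlength=n_levels + 1)[1:].astype(np.float64)
    s_i = np.zeros(n_levels)
    np.add.at(s_i, lv - 1, diff)
    n_total = n_i.sum()
    p_i = n_i / n_total

    present = p_i > 0
    ng = int(present.sum())
    i = np.arange(1, n_levels + 1, dtype=np.float64)

    denom_coarse = float(np.sum(p_i * s_i))
    coarseness = 1.0 / denom_coarse if denom_coarse > 0 else COARSENESS_CAP

    if ng <= 1:
        contrast = 0.0
    else:
        pij = np.subtract.outer(i[present], i[present]) ** 2
        cross = float(np.sum(np.outer(p_i[present], p_i[present]) * pij))
        contrast = cross * float(s_i.sum()) / (ng * (ng - 1) * n_total)

    ip = i[present] * p_i[present]
    denom_busy = float(np.sum(np.abs(np.subtract.outer(ip, ip))))
    busyness = denom_coarse / denom_busy if denom_busy > 0 else 0.0

    out = {
        "NGLDM Coarseness": float(coarseness),
        "NGLDM Contrast": float(contrast),
        "NGLDM Busyness": float(busyness),
    }
    return out, set()
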