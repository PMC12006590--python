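"""Grey-level zone-size matrix (GLZLM, a.k.a. GLSZM) features.

A zone is a maximal 26-connected region of constant grey level inside the
mask; zone sizes partition the mask.  Zone percentage divides the number of
zones by the number of voxels.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["zone_list", "glzlm_features"]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


def zone_list(levels: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(level, size) for every 26-connected constant-level zone.

    Kept as per-zone arrays rather than a dense level x size matrix: a single
    zone can span the whole VOI, which would make the dense form huge.
    """
    zlev, zsize = [], []
    for lv in np.unique(levels[mask]):
        lab, n = ndimage.label((levels == lv) & mask, structure=_CONN26)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        zlev.append(np.full(n, lv, dtype=np.int64))
        zsize.append(sizes.astype(np.int64))
    if not zlev:
        raise ValueError("mask contains no voxels")
    return np.concatenate(zlev), np.concatenate(zsize)


def glzlm_features(levels: np.ndarray, mask: np.ndarray, n_levels: int = 64,
                   ) -> tuple[dict[str, float], set[str]]:
    lv, sz = zone_list(levels, mask)
    nz = float(len(lv))
    i = lv.astype(np.float64)
    s = sz.astype(np.float64)
    n_vox = int(mask.sum())

    out = {
        "GLZLM SZE": float(np.sum(1.0 / (s * s)) / nz),
        "GLZLM LZE": float(np.sum(s * s) / nz),
        "GLZLM LGZE": float(np.sum(1.0 / (i * i)) / nz),
        "GLZLM HGZE": float(np.sum(i * i) / nz),
        "GLZLM SZLGE": float(np.sum(1.0 / (i * i * s * s)) / nz),
        "GLZLM SZHGE": float(np.sum(i * i / (s * s)) / nz),
        "GLZLM LZLGE": float(np.sum(s * s / (i * i)) / nz),
        "GLZLM LZHGE": float(np.sum(i * i * s * s) / nz),
        "GLZLM GLNU": float(np.sum(np.bincount(lv).astype(np.float64) ** 2) / nz),
        "GLZLM ZLNU": float(np.sum(np.bincount(sz).astype(np.float64) ** 2) / nz),
        "GLZLM ZP": float(nz / n_vox),
    }
    return out, set()
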