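"""Grey-level co-occurrence matrix (GLCM) features.

Level pairs at distance 1 are pooled over the 13 unique 3D directions before
normalisation (merged strategy) and symmetrised, giving one joint probability
matrix p(i, j) per VOI.
"""

from __future__ import annotations

import numpy as np

from .catalog import DEGENERATE
from ._directions import DIRECTIONS_13, shifted_slices

__all__ = ["glcm_matrix", "glcm_features"]


def glcm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int = 64,
                directions=DIRECTIONS_13) -> np.ndarray:
    """Symmetric, normalised co-occurrence matrix (entries sum to 1)."""
    counts = np.zeros(n_levels * n_levels, dtype=np.int64)
    for off in directions:
        sa, sb = shifted_slices(levels.shape, off)
        valid = mask[sa] & mask[sb]
        a = levels[sa][valid] - 1
        b = levels[sb][valid] - 1
        counts += np.bincount(a * n_levels + b, minlength=n_levels * n_levels)
    C = counts.reshape(n_levels, n_levels).astype(np.float64)
    C = C + C.T
    total = C.sum()
    if total == 0:
        raise ValueError("mask has no neighbouring voxel pairs")
    return C / total


def glcm_features(levels: np.ndarray, mask: np.ndarray, n_levels: int = 64,
                  directions=DIRECTIONS_13) -> tuple[dict[str, float], set[str]]:
    p = glcm_matrix(levels, mask, n_levels, directions)
    i, j = np.indices(p.shape) + 1
    diff = i - j
    nz = p[p > 0]

    out = {
        "GLCM homogeneity": float(np.sum(p / (1.0 + diff * diff))),
        "GLCM energy": float(np.sum(p * p)),
        "GLCM contrast": float(np.sum(p * diff * diff)),
        "GLCM dissimilarity": float(np.sum(p * np.abs(diff))),
        "GLCM entropy log2": float(-np.sum(nz * np.log2(nz))),
        "GLCM entropy log10": float(-np.sum(nz * np.log10(nz))),
    }
    # marginals are equal by symmetry
    px = p.sum(axis=1)
    mu = float(np.sum(np.arange(1, n_levels + 1) * px))
    var = float(np.sum((np.arange(1, n_levels + 1) - mu) ** 2 * px))
    if var == 0.0:
        out["GLCM correlation"] = DEGENERATE  # single grey level: 0/0
    else:
        out["GLCM correlation"] = float(np.sum(p * (i - mu) * (j - mu)) / var)
    degen = {k for k, v in out.items() if np.isnan(v)}
    return out, degen
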