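"""Grey-level run-length matrix (GLRLM) features.

Runs (maximal collinear stretches of one grey level inside the mask) are
pooled over the 13 unique 3D directions before the matrix statistics are
formed.  Run percentage divides the number of runs by voxels x directions.
"""

from __future__ import annotations

import numpy as np

from ._directions import DIRECTIONS_13

__all__ = ["glrlm_matrix", "glrlm_features"]


def _runs_one_direction(levels: np.ndarray, mask: np.ndarray, direction,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """(run level, run length) arrays for one direction.

    Voxels are grouped into lattice lines p - t*d (t the coordinate along the
    first nonzero axis of d) and sorted along t; breaks in t-adjacency or
    level start a new run.
    """
    pts = np.argwhere(mask)
    if pts.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    lev = levels[mask]  # argwhere and boolean indexing share C order
    d = np.asarray(direction)
    axis = int(np.nonzero(d)[0][0])
    t = pts[:, axis] * d[axis]
    line = pts - t[:, None] * d
    order = np.lexsort((t, line[:, 2], line[:, 1], line[:, 0]))
    t = t[order]
    lev = lev[order]
    line = line[order]
    new_run = np.ones(len(t), dtype=bool)
    same_line = (line[1:] == line[:-1]).all(axis=1)
    new_run[1:] = ~(same_line & (np.diff(t) == 1) & (lev[1:] == lev[:-1]))
    run_id = np.cumsum(new_run) - 1
    lengths = np.bincount(run_id)
    run_levels = lev[new_run]
    return run_levels, lengths


def glrlm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int = 64,
                 directions=DIRECTIONS_13) -> np.ndarray:
    """Run-length counts R[level-1, length-1], pooled over directions."""
    max_len = max(levels.shape)
    R = np.zeros((n_levels, max_len), dtype=np.int64)
    for d in directions:
        rl, ln = _runs_one_direction(levels, mask, d)
        np.add.at(R, (rl - 1, ln - 1), 1)
    return R


def glrlm_features(levels: np.ndarray, mask: np.ndarray, n_levels: int = 64,
                   directions=DIRECTIONS_13) -> tuple[dict[str, float], set[str]]:
    R = glrlm_matrix(levels, mask, n_levels, directions).astype(np.float64)
    nr = R.sum()
    if nr == 0:
        raise ValueError("mask contains no voxels")
    i = np.arange(1, n_levels + 1)[:, None].astype(np.float64)
    j = np.arange(1, R.shape[1] + 1)[None, :].astype(np.float64)
    n_vox = int(mask.sum())

    out = {
        "GLRLM SRE": float(np.sum(R / (j * j)) / nr),
        "GLRLM LRE": float(np.sum(R * j * j) / nr),
        "GLRLM LGRE": float(np.sum(R / (i * i)) / nr),
        "GLRLM HGRE": float(np.sum(R * i * i) / nr),
        "GLRLM SRLGE": float(np.sum(R / (i * i * j * j)) / nr),
        "GLRLM SRHGE": float(np.sum(R * i * i / (j * j)) / nr),
        "GLRLM LRLGE": float(np.sum(R * j * j / (i * i)) / nr),
        "GLRLM LRHGE": float(np.sum(R * i * i * j * j) / nr),
        "GLRLM GLNU": float(np.sum(R.sum(axis=1) ** 2) / nr),
        "GLRLM RLNU": float(np.sum(R.sum(axis=0) ** 2) / nr),
        "GLRLM RP": float(nr / (n_vox * len(directions))),
    }
    return out, set()
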