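"""Independent brute-force oracles for the texture matrices.

Everything here is computed by direct enumeration over voxels — explicit
loops, no pooled shortcuts, no shared code with the package — so that the
vectorised implementations can be checked against first principles.
"""

from collections import Counter
from itertools import product

import numpy as np

NEIGHBOURS_26 = [d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]


def _in(shape, p):
    return all(0 <= c < n for c, n in zip(p, shape))


def bf_glcm(levels, mask, n_levels, directions):
    """Symmetric pooled co-occurrence probabilities as a Counter."""
    pairs = Counter()
    for p in zip(*np.nonzero(mask)):
        for d in directions:
            q = tuple(c + o for c, o in zip(p, d))
            if _in(mask.shape, q) and mask[q]:
                a, b = int(levels[p]), int(levels[q])
                pairs[(a, b)] += 1
                pairs[(b, a)] += 1
    total = sum(pairs.values())
    return {k: v / total for k, v in pairs.items()}


def bf_glcm_features(levels, mask, n_levels, directions):
    p = bf_glcm(levels, mask, n_levels, directions)
    homog = sum(v / (1 + (i - j) ** 2) for (i, j), v in p.items())
    energy = sum(v * v for v in p.values())
    contrast = sum(v * (i - j) ** 2 for (i, j), v in p.items())
    dissim = sum(v * abs(i - j) for (i, j), v in p.items())
    ent2 = -sum(v * np.log2(v) for v in p.values() if v > 0)
    ent10 = -sum(v * np.log10(v) for v in p.values() if v > 0)
    mu = sum(i * v for (i, _), v in p.items())
    var = sum((i - mu) ** 2 * v for (i, _), v in p.items())
    corr = (sum((i - mu) * (j - mu) * v for (i, j), v in p.items()) / var
            if var > 0 else float("nan"))
    return {"GLCM homogeneity": homog, "GLCM energy": energy,
            "GLCM contrast": contrast, "GLCM dissimilarity": dissim,
            "GLCM entropy log2": ent2, "GLCM entropy log10": ent10,
            "GLCM correlation": corr}


def bf_runs(levels, mask, direction):
    """All maximal runs for one direction as (level, length) tuples."""
    runs = []
    for p in zip(*np.nonzero(mask)):
        prev = tuple(c - o for c, o in zip(p, direction))
        if _in(mask.shape, prev) and mask[prev] and levels[prev] == levels[p]:
            continue  # not a run start
        length, q = 0, p
        while _in(mask.shape, q) and mask[q] and levels[q] == levels[p]:
            length += 1
            q = tuple(c + o for c, o in zip(q, direction))
        runs.append((int(levels[p]), length))
    return runs


def bf_glrlm_features(levels, mask, n_levels, directions):
    runs = []
    for d in directions:
        runs.extend(bf_runs(levels, mask, d))
    nr = len(runs)
    nvox = int(mask.sum())
    sre = sum(1 / j**2 for _, j in runs) / nr
    lre = sum(j**2 for _, j in runs) / nr
    lgre = sum(1 / i**2 for i, _ in runs) / nr
    hgre = sum(i**2 for i, _ in runs) / nr
    srlge = sum(1 / (i**2 * j**2) for i, j in runs) / nr
    srhge = sum(i**2 / j**2 for i, j in runs) / nr
    lrlge = sum(j**2 / i**2 for i, j in runs) / nr
    lrhge = sum(i**2 * j**2 for i, j in runs) / nr
    by_level = Counter(i for i, _ in runs)
    by_len = Counter(j for _, j in runs)
    glnu = sum(c**2 for c in by_level.values()) / nr
    rlnu = sum(c**2 for c in by_len.values()) / nr
    return {"GLRLM SRE": sre, "GLRLM LRE": lre, "GLRLM LGRE": lgre,
            "GLRLM HGRE": hgre, "GLRLM SRLGE": srlge, "GLRLM SRHGE": srhge,
            "GLRLM LRLGE": lrlge, "GLRLM LRHGE": lrhge, "GLRLM GLNU": glnu,
            "GLRLM RLNU": rlnu, "GLRLM RP": nr / (nvox * len(directions))}


def bf_zones(levels, mask):
    """(level, size) of every 26-connected constant-level zone via BFS."""
    seen = np.zeros(mask.shape, dtype=bool)
    zones = []
    for p in zip(*np.nonzero(mask)):
        if seen[p]:
            continue
        lv = levels[p]
        stack, size = [p], 0
        seen[p] = True
        while stack:
            q = stack.pop()
            size += 1
            for d in NEIGHBOURS_26:
                r = tuple(c + o for c, o in zip(q, d))
                if (_in(mask.shape, r) and mask[r] and not seen[r]
                        and levels[r] == lv):
                    seen[r] = True
                    stack.append(r)
        zones.append((int(lv), size))
    return zones


def bf_glzlm_features(levels, mask, n_levels):
    zones = bf_zones(levels, mask)
    nz = len(zones)
    nvox = int(mask.sum())
    by_level = Counter(i for i, _ in zones)
    by_size = Counter(s for _, s in zones)
    return {
        "GLZLM SZE": sum(1 / s**2 for _, s in zones) / nz,
        "GLZLM LZE": sum(s**2 for _, s in zones) / nz,
        "GLZLM LGZE": sum(1 / i**2 for i, _ in zones) / nz,
        "GLZLM HGZE": sum(i**2 for i, _ in zones) / nz,
        "GLZLM SZLGE": sum(1 / (i**2 * s**2) for i, s in zones) / nz,
        "GLZLM SZHGE": sum(i**2 / s**2 for i, s in zones) / nz,
        "GLZLM LZLGE": sum(s**2 / i**2 for i, s in zones) / nz,
        "GLZLM LZHGE": sum(i**2 * s**2 for i, s in zones) / nz,
        "GLZLM GLNU": sum(c**2 for c in by_level.values()) / nz,
        "GLZLM ZLNU": sum(c**2 for c in by_size.values()) / nz,
        "GLZLM ZP": nz / nvox,
    }


def bf_ngldm_features(levels, mask, n_levels, cap=1e6):
    per_level_n = Counter()
    per_level_s = Counter()
    for p in zip(*np.nonzero(mask)):
        neigh = []
        for d in NEIGHBOURS_26:
            q = tuple(c + o for c, o in zip(p, d))
            if _in(mask.shape, q) and mask[q]:
                neigh.append(int(levels[q]))
        if not neigh:
            continue
        lv = int(levels[p])
        per_level_n[lv] += 1
        per_level_s[lv] += abs(lv - sum(neigh) / len(neigh))
    n_total = sum(per_level_n.values())
    p_i = {i: n / n_total for i, n in per_level_n.items()}
    s_i = dict(per_level_s)
    denom = sum(p_i[i] * s_i.get(i, 0.0) for i in p_i)
    coarseness = 1.0 / denom if denom > 0 else cap
    ng = len(p_i)
    if ng <= 1:
        contrast = 0.0
    else:
        cross = sum(p_i[i1] * p_i[i2] * (i1 - i2) ** 2
                    for i1 in p_i for i2 in p_i)
        contrast = cross * sum(s_i.values()) / (ng * (ng - 1) * n_total)
    busy_den = sum(abs(i1 * p_i[i1] - i2 * p_i[i2]) for i1 in p_i for i2 in p_i)
    busyness = denom / busy_den if busy_den > 0 else 0.0
    return {"NGLDM Coarseness": coarseness, "NGLDM Contrast": contrast,
            "NGLDM Busyness": busyness}
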