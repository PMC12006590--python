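"""Histogram descriptors of the discretised grey levels.

Probabilities are taken over the full bin range of the scheme; entropies use
the 0 log 0 = 0 convention, and the moments are population moments of the
level distribution (affine-invariant, so identical on levels or bin centres).
"""

from __future__ import annotations

import numpy as np

from .catalog import DEGENERATE
from .discretise import DiscretisationScheme

__all__ = ["histogram_features"]


def histogram_features(levels: np.ndarray, scheme: DiscretisationScheme,
                       ) -> tuple[dict[str, float], set[str]]:
    levels = np.asarray(levels).ravel()
    if levels.size == 0:
        raise ValueError("no levels supplied")
    counts = np.bincount(levels, minlength=scheme.n_bins + 1)[1:]
    p = counts / counts.sum()
    nz = p[p > 0]

    out = {
        "Discretised histogram energy": float(np.sum(p * p)),
        "Discretised histogram entropy log2": float(-np.sum(nz * np.log2(nz))),
        "Discretised histogram entropy log10": float(-np.sum(nz * np.log10(nz))),
    }

    mean = float(np.sum(p * np.arange(1, scheme.n_bins + 1)))
    var = float(np.sum(p * (np.arange(1, scheme.n_bins + 1) - mean) ** 2))
    if var == 0.0:
        out["Discretised histogram Skewness"] = DEGENERATE
        out["Discretised histogram Kurtosis"] = DEGENERATE
        out["Discretised histogram Excess Kurtosis"] = DEGENERATE
    else:
        i = np.arange(1, scheme.n_bins + 1)
        m3 = float(np.sum(p * (i - mean) ** 3))
        m4 = float(np.sum(p * (i - mean) ** 4))
        out["Discretised histogram Skewness"] = m3 / var ** 1.5
        out["Discretised histogram Kurtosis"] = m4 / var ** 2
        out["Discretised histogram Excess Kurtosis"] = m4 / var ** 2 - 3.0

    degen = {k for k, v in out.items() if np.isnan(v)}
    return out, degen
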