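"""Fixed-bin-width SUV discretisation.

The protocol discretises SUVs over a fixed 0-20 SUV range into 64 bins,
i.e. a bin width of 0.3125 SUV (reported rounded as 0.3 SUV/bin).  Fixed bin
width (rather than a fixed bin count per VOI) keeps grey levels comparable
across VOIs of different volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DiscretisationScheme", "discretise"]


@dataclass(frozen=True)
class DiscretisationScheme:
    n_bins: int = 64
    lower: float = 0.0
    upper: float = 20.0

    def __post_init__(self):
        if self.n_bins < 1:
            raise ValueError("need at least one bin")
        if not self.upper > self.lower:
            raise ValueError("upper bound must exceed lower bound")

    @property
    def bin_width(self) -> float:
        return (self.upper - self.lower) / self.n_bins

    def bin_center(self, level):
        """SUV value at the centre of grey level ``level`` (1-based)."""
        return self.lower + (np.asarray(level) - 0.5) * self.bin_width


def discretise(values, scheme: DiscretisationScheme = DiscretisationScheme()) -> np.ndarray:
    """Map SUVs to integer grey levels 1..n_bins.

    ``level = floor((x - lower) / bin_width) + 1``, clamped to [1, n_bins];
    the upper bound itself maps to the top level.
    """
    x = np.asarray(values, dtype=np.float64)
    if not np.isfinite(x).all():
        raise ValueError("discretise requires finite values")
    levels = np.floor((x - scheme.lower) / scheme.bin_width).astype(np.int64) + 1
    return np.clip(levels, 1, scheme.n_bins)
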