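"""Conventional SUV statistics and their discretised counterparts.

Raw statistics are computed on the in-mask SUVs; discretised statistics on
the bin-centre values of the discretised levels, so they stay in SUV units.
Raw skewness/kurtosis are population moments; the discretised variants use
the bias-corrected sample estimators, which is what distinguishes them
numerically from the histogram moments of the same levels.
Kurtosis is the raw fourth standardised moment; excess kurtosis subtracts 3.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, stats

from ..image import VoxelImage, Mask
from .catalog import DEGENERATE
from .discretise import DiscretisationScheme, discretise

__all__ = ["intensity_features", "discretised_intensity_features", "suv_peak"]


def _sphere_kernel(volume_ml: float, spacing) -> np.ndarray:
    """Boolean kernel of voxels whose centres lie in a sphere of the given
    volume (radius r = (3V/4pi)^(1/3) mm)."""
    r = (3.0 * volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    half = [int(np.floor(r / s)) for s in spacing]
    ax = [np.arange(-h, h + 1) * s for h, s in zip(half, spacing)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    return (gx * gx + gy * gy + gz * gz) <= r * r


def suv_peak(image: VoxelImage, mask: Mask, volume_ml: float) -> float:
    """Max over in-mask voxels of the mean SUV within a sphere of
    ``volume_ml`` centred on the voxel.  The sphere may reach outside the
    mask; parts outside the image are excluded from the mean."""
    kernel = _sphere_kernel(volume_ml, image.spacing)
    pad = [k // 2 for k in kernel.shape]
    idx = np.argwhere(mask.values)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad + 1, image.shape)
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    vals = image.values[box]
    kf = kernel.astype(np.float64)
    total = ndimage.convolve(vals, kf, mode="constant", cval=0.0)
    norm = ndimage.convolve(np.ones_like(vals), kf, mode="constant", cval=0.0)
    means = total / norm
    return float(means[mask.values[box]].max())


def _moment_stats(x: np.ndarray, bias: bool) -> tuple[float, float, float]:
    """(skewness, kurtosis, excess kurtosis); NaN when undefined."""
    if x.size < 2 or np.ptp(x) == 0.0:
        return DEGENERATE, DEGENERATE, DEGENERATE
    skew = stats.skew(x, bias=bias)
    kurt_excess = stats.kurtosis(x, fisher=True, bias=bias)
    if not (np.isfinite(skew) and np.isfinite(kurt_excess)):
        return DEGENERATE, DEGENERATE, DEGENERATE
    return float(skew), float(kurt_excess) + 3.0, float(kurt_excess)


def _base_stats(x: np.ndarray, volume_ml: float, prefix: str = "SUV") -> dict[str, float]:
    q1, q2, q3 = np.percentile(x, [25, 50, 75])
    return {
        f"{prefix}min": float(x.min()),
        f"{prefix}mean": float(x.mean()),
        f"{prefix}std": float(x.std(ddof=0)),
        f"{prefix}max": float(x.max()),
        f"{prefix}Q1": float(q1),
        f"{prefix}Q2": float(q2),
        f"{prefix}Q3": float(q3),
    }


def intensity_features(image: VoxelImage, mask: Mask) -> tuple[dict[str, float], set[str]]:
    """Raw-SUV statistics: min/mean/std/max, quartiles, population skewness
    and kurtosis, SUVpeak (0.5 and 1.0 ml) and TLSRE = SUVmean x volume."""
    if mask.voxel_count == 0:
        raise ValueError("empty mask")
    x = image.values[mask.values]
    out = _base_stats(x, mask.volume_ml)
    skew, kurt, exc = _moment_stats(x, bias=True)
    out["SUV Skewness"] = skew
    out["SUV Kurtosis"] = kurt
    out["SUV Excess Kurtosis"] = exc
    out["SUVpeak 0.5 ml"] = suv_peak(image, mask, 0.5)
    out["SUVpeak 1.0 ml"] = suv_peak(image, mask, 1.0)
    out["TLSRE"] = out["SUVmean"] * mask.volume_ml
    degen = {k for k, v in out.items() if isinstance(v, float) and np.isnan(v)}
    return out, degen


def discretised_intensity_features(image: VoxelImage, mask: Mask,
                                   scheme: DiscretisationScheme,
                                   ) -> tuple[dict[str, float], set[str]]:
    """The same statistics on the bin-centre image of the discretised levels
    (sample skewness/kurtosis; no separate excess-kurtosis entry — that lives
    with the histogram moments)."""
    if mask.voxel_count == 0:
        raise ValueError("empty mask")
    levels_img = discretise(image.values, scheme)
    centers_img = image.like(scheme.bin_center(levels_img), unit="SUV")
    x = centers_img.values[mask.values]
    out = {f"Discretised {k}": v for k, v in _base_stats(x, mask.volume_ml).items()}
    skew, kurt, _ = _moment_stats(x, bias=False)
    out["Discretised SUV Skewness"] = skew
    out["Discretised SUV Kurtosis"] = kurt
    out["Discretised SUVpeak 0.5 ml"] = suv_peak(centers_img, mask, 0.5)
    out["Discretised SUVpeak 1.0 ml"] = suv_peak(centers_img, mask, 1.0)
    out["Discretised TLSRE"] = out["Discretised SUVmean"] * mask.volume_ml
    degen = {k for k, v in out.items() if isinstance(v, float) and np.isnan(v)}
    return out, degen
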