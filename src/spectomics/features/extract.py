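"""Assemble the complete 67-feature vector for one (image, mask) pair."""

from __future__ import annotations

import numpy as np

from ..image import VoxelImage, Mask
from .catalog import FeatureCatalog, FeatureVector, load_catalog
from .discretise import DiscretisationScheme, discretise
from .intensity import intensity_features, discretised_intensity_features
from .histogram import histogram_features
from .shape import shape_features
from .glcm import glcm_features
from .glrlm import glrlm_features
from .glzlm import glzlm_features
from .ngldm import ngldm_features

__all__ = ["extract_all"]


def _bounding_box(mask: np.ndarray, pad: int = 1):
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad + 1, mask.shape)
    return tuple(slice(a, b) for a, b in zip(lo, hi))


def extract_all(image: VoxelImage, mask: Mask,
                scheme: DiscretisationScheme = DiscretisationScheme(),
                catalog: FeatureCatalog | None = None,
                provenance: dict | None = None) -> FeatureVector:
    """Compute every catalogue feature.

    Texture families (GLCM/GLRLM/GLZLM/NGLDM) and histogram descriptors are
    computed on the discretised levels restricted to the mask bounding box;
    SUV statistics on the raw in-mask SUVs.  Degenerate masks (constant
    intensity, single grey level) yield flagged NaN entries, never omissions.
    """
    if catalog is None:
        catalog = load_catalog()
    if not mask.same_grid_as(image):
        raise ValueError("mask and image are not on the same grid")
    if mask.voxel_count == 0:
        raise ValueError("empty mask")

    values: dict[str, float] = {}
    degenerate: set[str] = set()

    for part, dg in (intensity_features(image, mask),
                     discretised_intensity_features(image, mask, scheme)):
        values.update(part)
        degenerate |= dg

    box = _bounding_box(mask.values)
    lv = discretise(image.values[box], scheme)
    mk = mask.values[box]

    part, dg = histogram_features(lv[mk], scheme)
    values.update(part); degenerate |= dg
    part, dg = shape_features(mask)
    values.update(part); degenerate |= dg
    if mask.voxel_count >= 2:
        part, dg = glcm_features(lv, mk, scheme.n_bins)
        values.update(part); degenerate |= dg
        part, dg = ngldm_features(lv, mk, scheme.n_bins)
        values.update(part); degenerate |= dg
    else:
        for name in ("GLCM homogeneity", "GLCM energy", "GLCM contrast",
                     "GLCM correlation", "GLCM entropy log10", "GLCM entropy log2",
                     "GLCM dissimilarity", "NGLDM Coarseness", "NGLDM Contrast",
                     "NGLDM Busyness"):
            values[name] = float("nan")
            degenerate.add(name)
    part, dg = glrlm_features(lv, mk, scheme.n_bins)
    values.update(part); degenerate |= dg
    part, dg = glzlm_features(lv, mk, scheme.n_bins)
    values.update(part); degenerate |= dg

    vec = FeatureVector(values=values, degenerate=degenerate,
                        provenance=dict(provenance or {}))
    vec.check_complete(catalog)
    return vec
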