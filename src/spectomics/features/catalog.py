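"""The 67-name feature catalogue and the FeatureVector container.

The catalogue ships as a versioned JSON data file assembled from the feature
families of the LIFEx v6.3 texture set: conventional SUV statistics (incl.
SUVpeak and TLSRE), their discretised counterparts, histogram descriptors,
shape, GLCM, GLRLM, NGLDM and GLZLM.  Alias spellings that occur in the
published tables are normalised on load.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

__all__ = ["FeatureCatalog", "FeatureVector", "load_catalog", "DEGENERATE"]

#: Sentinel stored for features that are undefined on a degenerate region
#: (e.g. skewness of a constant VOI).  Kept as NaN so tables stay numeric;
#: the accompanying ``degenerate`` set records which entries are flagged.
DEGENERATE = float("nan")


@dataclass(frozen=True)
class FeatureCatalog:
    version: str
    features: tuple[str, ...]
    families: dict[str, tuple[str, ...]]
    aliases: dict[str, str]

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def __contains__(self, name: str) -> bool:
        return self.canonical(name) in self._feature_set

    @property
    def _feature_set(self) -> frozenset:
        return frozenset(self.features)

    def canonical(self, name: str) -> str:
        return self.aliases.get(name, name)

    def family_of(self, name: str) -> str:
        name = self.canonical(name)
        for fam, members in self.families.items():
            if name in members:
                return fam
        raise KeyError(name)


def load_catalog() -> FeatureCatalog:
    raw = json.loads(
        resources.files("spectomics.data").joinpath("feature_catalog.json").read_text())
    return FeatureCatalog(
        version=raw["version"],
        features=tuple(raw["features"]),
        families={k: tuple(v) for k, v in raw["families"].items()},
        aliases=dict(raw["aliases"]),
    )


@dataclass
class FeatureVector:
    """All catalogue features for one (image, mask) pair.

    ``values`` is complete over the catalogue; entries whose definition fails
    on the region (constant intensities, single grey level, ...) hold NaN and
    are listed in ``degenerate`` — never silently omitted.
    """

    values: dict[str, float]
    degenerate: set[str] = field(default_factory=set)
    provenance: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def is_degenerate(self, name: str) -> bool:
        return name in self.degenerate

    def check_complete(self, catalog: FeatureCatalog) -> None:
        missing = set(catalog.features) - set(self.values)
        extra = set(self.values) - set(catalog.features)
        if missing or extra:
            raise ValueError(f"feature vector mismatch: missing={sorted(missing)}, "
                             f"extra={sorted(extra)}")
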