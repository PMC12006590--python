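"""The two robustness screens and the combined feature reduction.

Volume dependency: each feature's curve over the expanding sphere series is
classified as *converging* (stable beyond ~25 ml), *correlated* (monotone
trend in the tail) or *random*.  The published protocol classified curves by
visual inspection; here an explicit tail-stability rule replaces the eyeball
so the outcome is reproducible, with both parameters exposed.

Repeatability: the coefficient of variation of each feature across repeat
scans of each Revolver insert, screened at 10%.

Reduction: a feature is excluded if it is non-converging (unless on the
explicit keep-exception list) or fails the CoV screen in any insert.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .features.catalog import FeatureCatalog, load_catalog

__all__ = [
    "cov_percent", "cov_table", "repeatability_flags",
    "VolumeCurve", "DependencyLabel", "volume_curves", "classify_dependency",
    "ReductionResult", "reduce_features", "load_reference_tables",
]

COV_THRESHOLD_PCT = 10.0
CONVERGENCE_VOLUME_ML = 25.0
TAIL_TOLERANCE = 0.10
TAIL_RHO = 0.8


# ---------------------------------------------------------------------------
# repeatability

def cov_percent(values) -> float:
    """100 x sample standard deviation / |mean|; NaN flags a zero mean."""
    x = np.asarray(values, dtype=np.float64)
    if x.size < 2:
        raise ValueError("CoV needs at least two repeats")
    mean = x.mean()
    if mean == 0.0:
        return float("nan")
    return float(100.0 * x.std(ddof=1) / abs(mean))


def cov_table(repeats: dict[str, pd.DataFrame], min_valid: int = 2) -> pd.DataFrame:
    """Per-feature, per-insert CoV%.

    ``repeats`` maps an insert label to a (repeat x feature) table.  Flagged
    degenerate values (NaN) are dropped from the CoV rather than treated as
    zero; a cell with fewer than ``min_valid`` valid repeats is NaN
    (unevaluable).
    """
    out = {}
    for insert, df in repeats.items():
        col = {}
        for feat in df.columns:
            vals = df[feat].to_numpy(dtype=np.float64)
            vals = vals[np.isfinite(vals)]
            col[feat] = cov_percent(vals) if vals.size >= min_valid else float("nan")
        out[insert] = col
    return pd.DataFrame(out)


def repeatability_flags(cov_df: pd.DataFrame,
                        threshold: float = COV_THRESHOLD_PCT) -> pd.DataFrame:
    """Screen the CoV table: a feature fails overall iff CoV > threshold in
    at least one insert.  Returns per-feature ``n_failing_inserts``, ``fail``
    and ``unevaluable`` (no insert could be evaluated)."""
    failing = (cov_df > threshold)
    evaluable = cov_df.notna()
    return pd.DataFrame({
        "n_failing_inserts": failing.sum(axis=1).astype(int),
        "fail": failing.any(axis=1),
        "unevaluable": ~evaluable.any(axis=1),
    })


# ---------------------------------------------------------------------------
# volume dependency

@dataclass(frozen=True)
class DependencyLabel:
    label: str  # "converging" | "correlated" | "random"
    convergence_volume: float | None = None

    def __post_init__(self):
        if self.label not in ("converging", "correlated", "random"):
            raise ValueError(f"unknown dependency label {self.label!r}")


@dataclass
class VolumeCurve:
    feature: str
    volumes_ml: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.volumes_ml = np.asarray(self.volumes_ml, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.volumes_ml.shape != self.values.shape:
            raise ValueError("volumes and values differ in length")
        if np.any(np.diff(self.volumes_ml) <= 0):
            raise ValueError("volumes must be strictly increasing")


def volume_curves(table: pd.DataFrame, volume_column: str = "volume_ml",
                  ) -> list[VolumeCurve]:
    """One curve per feature column, sorted by VOI volume regardless of row
    order.  NaN values (degenerate VOIs) are kept as gaps in the curve."""
    if len(table) < 3:
        raise ValueError("need at least three VOIs for volume curves")
    df = table.sort_values(volume_column)
    vols = df[volume_column].to_numpy(dtype=np.float64)
    return [VolumeCurve(feat, vols, df[feat].to_numpy(dtype=np.float64))
            for feat in df.columns if feat != volume_column]


def classify_dependency(curve: VolumeCurve,
                        v_conv: float = CONVERGENCE_VOLUME_ML,
                        tail_tol: float = TAIL_TOLERANCE,
                        tail_rho: float = TAIL_RHO) -> DependencyLabel:
    """Tail-stability rule.

    *converging*: every tail value (volume >= v_conv) lies within
    ``tail_tol x (max - min over the whole curve)`` of the tail median; the
    convergence volume is the smallest volume from which that band holds.
    Otherwise *correlated* if the tail has a monotone trend (Spearman
    |rho| >= tail_rho), else *random*.  Degenerate gaps (NaN) are ignored;
    a flat curve converges trivially at its first volume.
    """
    ok = np.isfinite(curve.values)
    vols, vals = curve.volumes_ml[ok], curve.values[ok]
    if vals.size < 3:
        raise ValueError(f"curve for {curve.feature!r} has fewer than 3 valid points")
    tail = vols >= v_conv
    if not tail.any() or tail.all():
        raise ValueError("curve must span volumes below and above v_conv")

    spread = float(vals.max() - vals.min())
    if spread == 0.0:
        return DependencyLabel("converging", float(vols[0]))

    med = float(np.median(vals[tail]))
    within = np.abs(vals - med) <= tail_tol * spread
    if within[tail].all():
        # extend the stable band to smaller volumes while it keeps holding
        start = int(np.nonzero(tail)[0][0])
        while start > 0 and within[start - 1]:
            start -= 1
        return DependencyLabel("converging", float(vols[start]))

    rho = stats.spearmanr(vols[tail], vals[tail]).statistic
    if np.isfinite(rho) and abs(rho) >= tail_rho:
        return DependencyLabel("correlated", None)
    return DependencyLabel("random", None)


# ---------------------------------------------------------------------------
# reduction

@dataclass
class ReductionResult:
    table: pd.DataFrame  # per feature: label, fail, excluded_by, keep_list_exception
    retained: list[str] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return len(self.retained)


def reduce_features(catalog: FeatureCatalog,
                    labels: dict[str, DependencyLabel | str],
                    repeat_fail: dict[str, bool],
                    keep_exceptions: set[str] | None = None) -> ReductionResult:
    """Combine the two screens over the full catalogue.

    ``excluded_by`` is one of volume / cov / both / none; keep-exception
    features are never excluded (their flag is recorded instead).  Labels and
    flags must cover the catalogue exactly — a coverage gap is a hard error.
    """
    keep = {catalog.canonical(n) for n in (keep_exceptions or set())}
    names = list(catalog.features)
    missing = [n for n in names if n not in labels or n not in repeat_fail]
    if missing:
        raise ValueError(f"labels/flags missing for: {missing}")

    rows = []
    retained = []
    for name in names:
        lab = labels[name]
        lab = lab.label if isinstance(lab, DependencyLabel) else lab
        vol_bad = lab != "converging"
        cov_bad = bool(repeat_fail[name])
        excluded_by = {(False, False): "none", (True, False): "volume",
                       (False, True): "cov", (True, True): "both"}[(vol_bad, cov_bad)]
        exception = (vol_bad or cov_bad) and name in keep
        is_retained = excluded_by == "none" or exception
        if is_retained:
            retained.append(name)
        rows.append({"feature": name, "dependency": lab, "cov_fail": cov_bad,
                     "excluded_by": excluded_by,
                     "keep_list_exception": exception, "retained": is_retained})
    table = pd.DataFrame(rows).set_index("feature")
    return ReductionResult(table=table, retained=retained)


# ---------------------------------------------------------------------------
# published reference tables

@dataclass(frozen=True)
class ReferenceTables:
    """Transcriptions of the published screen outcomes for both
    radionuclides, normalised to catalogue names."""

    volume_dependent: dict[str, list[str]]
    cov_failures: dict[str, list[dict]]
    retained: dict[str, list[str]]
    keep_exceptions: dict[str, list[dict]]

    def exclusions(self, radionuclide: str) -> tuple[set[str], set[str]]:
        vol = set(self.volume_dependent[radionuclide])
        cov = {e["feature"] for e in self.cov_failures[radionuclide]}
        return vol, cov

    def keep_set(self, radionuclide: str) -> set[str]:
        return {e["feature"] for e in self.keep_exceptions[radionuclide]}


def _load_json(name: str) -> dict:
    return json.loads(resources.files("spectomics.data").joinpath(name).read_text())


def load_reference_tables(catalog: FeatureCatalog | None = None) -> ReferenceTables:
    catalog = catalog or load_catalog()
    vol = _load_json("tables/volume_dependent.json")
    cov = _load_json("tables/cov_failures.json")
    ret = _load_json("tables/retained.json")
    keep = _load_json("keep_exceptions.json")
    c = catalog.canonical
    return ReferenceTables(
        volume_dependent={r: [c(n) for n in vol[r]] for r in ("tc99m", "lu177")},
        cov_failures={r: [{**e, "feature": c(e["feature"])} for e in cov[r]]
                      for r in ("tc99m", "lu177")},
        retained={r: [c(n) for n in ret[r]] for r in ("tc99m", "lu177")},
        keep_exceptions={r: [{**e, "feature": c(e["feature"])} for e in keep[r]]
                         for r in ("tc99m", "lu177")},
    )


def replay_reduction(radionuclide: str,
                     catalog: FeatureCatalog | None = None,
                     tables: ReferenceTables | None = None) -> ReductionResult:
    """Re-run the reduction from the transcribed published screens."""
    catalog = catalog or load_catalog()
    tables = tables or load_reference_tables(catalog)
    vol, cov = tables.exclusions(radionuclide)
    labels = {n: "random" if n in vol else "converging" for n in catalog.features}
    fails = {n: n in cov for n in catalog.features}
    return reduce_features(catalog, labels, fails,
                           keep_exceptions=tables.keep_set(radionuclide))
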