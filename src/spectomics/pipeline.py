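"""End-to-end experiment: simulate -> segment -> extract -> reduce.

One ``RunConfig`` drives the whole protocol for one radionuclide: a uniform
phantom scan probed with the 29-sphere VOI series for volume dependency, and
three Revolver inserts (2.5/5/10 ml syringes) scanned four times each for
repeatability.  A run is reproducible from its config alone: every output
table is written deterministically and hashed into a manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import phantoms
from .image import VoxelImage, Mask, write_nifti
from .features import DiscretisationScheme, extract_all, load_catalog
from .segmentation import (SegmentationParams, rasterize_sphere,
                           spherical_voi_series, segment)
from . import robustness as rb

__all__ = ["RunConfig", "ReportBundle", "run_experiment", "validate_against_tables"]


@dataclass
class RunConfig:
    radionuclide: str = "tc99m"
    seed: int = 0
    out_dir: str = "results/run"

    # imaging model (None -> per-radionuclide default)
    voxel_size: float = 1.95
    psf_fwhm: float | None = None
    count_scale: float | None = None
    sample_noise: bool = True

    # activities (MBq; None -> protocol default for the radionuclide)
    uniform_activity_mbq: float | None = None
    revolver_background_mbq: float | None = None
    ratios: tuple = phantoms.DEFAULT_RATIOS

    # VOI series
    voi_d_min: float = 10.0
    voi_d_max: float = 122.0
    voi_step: float = 4.0

    # Revolver protocol
    syringe_volumes: tuple = (2.5, 5.0, 10.0)
    n_repeats: int = 4
    segmentation_method: str = "percent_max"
    segmentation_factor: float = 0.40

    # discretisation
    n_bins: int = 64
    suv_lower: float = 0.0
    suv_upper: float = 20.0

    # robustness thresholds
    cov_threshold: float = rb.COV_THRESHOLD_PCT
    v_conv: float = rb.CONVERGENCE_VOLUME_ML
    tail_tol: float = rb.TAIL_TOLERANCE

    # outputs
    make_plots: bool = False
    write_images: bool = False

    def __post_init__(self):
        if self.radionuclide not in phantoms.IMAGING_DEFAULTS:
            raise ValueError(f"unknown radionuclide {self.radionuclide!r}")
        self.ratios = tuple(float(r) for r in self.ratios)
        self.syringe_volumes = tuple(float(v) for v in self.syringe_volumes)

    @property
    def scheme(self) -> DiscretisationScheme:
        return DiscretisationScheme(self.n_bins, self.suv_lower, self.suv_upper)

    def imaging_model(self) -> phantoms.ImagingModel:
        base = phantoms.IMAGING_DEFAULTS[self.radionuclide]
        return phantoms.ImagingModel(
            psf_fwhm=base.psf_fwhm if self.psf_fwhm is None else self.psf_fwhm,
            count_scale=base.count_scale if self.count_scale is None else self.count_scale,
            voxel_size=self.voxel_size, seed=self.seed,
            sample_noise=self.sample_noise)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["ratios"] = list(d["ratios"])
        d["syringe_volumes"] = list(d["syringe_volumes"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class ReportBundle:
    config: RunConfig
    volume_table: pd.DataFrame
    dependency: pd.DataFrame
    revolver_table: pd.DataFrame
    cov: pd.DataFrame
    reduction: rb.ReductionResult
    manifest: dict
    warnings: list[str] = field(default_factory=list)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, float_format="%.12g")


def _uniform_stage(config: RunConfig, model, out: Path, files: list[Path],
                   warnings: list[str]):
    geom = phantoms.PhantomGeometry.uniform_cylinder()
    spec = phantoms.ActivitySpec.uniform(
        config.uniform_activity_mbq
        or phantoms.UNIFORM_ACTIVITY_MBQ[config.radionuclide], geom)
    truth = phantoms.build_uniform_phantom(geom, spec, config.voxel_size)
    scan = phantoms.simulate_scan(truth, model, spec)
    if config.write_images:
        p = write_nifti(scan, out / "uniform_scan.nii.gz",
                        sidecar={"radionuclide": config.radionuclide,
                                 "seed": model.seed,
                                 "psf_fwhm": model.psf_fwhm,
                                 "count_scale": model.count_scale})
        files.append(p)
    interior = phantoms.cylinder_interior_mask(geom, scan)
    series = spherical_voi_series((0.0, 0.0, 0.0), scan,
                                  config.voi_d_min, config.voi_d_max,
                                  config.voi_step, interior=interior)
    catalog = load_catalog()
    rows = []
    for diameter, mask in series:
        vec = extract_all(scan, mask, config.scheme, catalog)
        rows.append({"diameter_mm": diameter, "volume_ml": mask.volume_ml,
                     **{f: vec.values[f] for f in catalog.features}})
    table = pd.DataFrame(rows)

    curves = rb.volume_curves(table.drop(columns="diameter_mm"))
    dep_rows = []
    for curve in curves:
        try:
            lab = rb.classify_dependency(curve, config.v_conv, config.tail_tol)
            dep_rows.append({"feature": curve.feature, "label": lab.label,
                             "convergence_volume_ml": lab.convergence_volume})
        except ValueError:
            warnings.append(f"volume curve unevaluable for {curve.feature}")
            dep_rows.append({"feature": curve.feature, "label": "unevaluable",
                             "convergence_volume_ml": None})
    dependency = pd.DataFrame(dep_rows).set_index("feature")
    return table, dependency, series, scan


def _revolver_stage(config: RunConfig, model, out: Path, files: list[Path],
                    warnings: list[str]):
    catalog = load_catalog()
    rows = []
    for k, syr_ml in enumerate(config.syringe_volumes):
        geom = phantoms.PhantomGeometry.revolver(syr_ml)
        spec = phantoms.ActivitySpec.revolver(
            config.revolver_background_mbq
            or phantoms.REVOLVER_BACKGROUND_MBQ[config.radionuclide],
            geom, config.ratios)
        insert_model = dataclasses.replace(model, seed=model.seed + 100 * (k + 1))
        scans = phantoms.generate_repeat_series(geom, spec, insert_model,
                                                config.n_repeats, config.voxel_size)
        for r, scan in enumerate(scans):
            if config.segmentation_method == "percent_max":
                search = rasterize_sphere(geom.insert_center, 100.0, scan)
                params = SegmentationParams("percent_max", config.segmentation_factor,
                                            search_region=search)
            else:
                bg = phantoms.background_region_mask(geom, scan)
                params = SegmentationParams("adaptive_background",
                                            config.segmentation_factor,
                                            background_region=bg)
            mask = segment(scan, params, geom.insert_center)
            vec = extract_all(scan, mask, config.scheme, catalog)
            if config.write_images:
                p = write_nifti(mask, out / f"revolver_{syr_ml}ml_rep{r}_mask.nii.gz")
                files.append(p)
            rows.append({"insert_ml": syr_ml, "repeat": r,
                         "segmented_volume_ml": mask.volume_ml,
                         **{f: vec.values[f] for f in catalog.features}})
    table = pd.DataFrame(rows)
    repeats = {
        f"{syr} ml": table[table["insert_ml"] == syr].set_index("repeat")[
            list(catalog.features)]
        for syr in config.syringe_volumes}
    cov = rb.cov_table(repeats)
    if config.n_repeats < 2:
        warnings.append("fewer than two repeats: CoV screen unevaluable")
    return table, cov


def _plot_volume_curves(table: pd.DataFrame, out: Path, files: list[Path]) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    catalog = load_catalog()
    feats = list(catalog.features)
    per_page = 20
    vols = table["volume_ml"].to_numpy()
    for page in range(0, len(feats), per_page):
        chunk = feats[page:page + per_page]
        fig, axes = plt.subplots(5, 4, figsize=(14, 12))
        for ax, feat in zip(axes.ravel(), chunk):
            ax.plot(vols, table[feat].to_numpy(), "o-", ms=2.5, lw=0.8)
            ax.set_title(feat, fontsize=7)
            ax.tick_params(labelsize=6)
        for ax in axes.ravel()[len(chunk):]:
            ax.axis("off")
        fig.supxlabel("VOI volume (ml)", fontsize=9)
        fig.tight_layout()
        p = out / f"volume_curves_{page // per_page + 1}.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        files.append(p)


def run_experiment(config: RunConfig) -> ReportBundle:
    """Execute the full protocol and write the report bundle to
    ``config.out_dir``.  Reruns with the same config produce bit-identical
    manifests."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = config.imaging_model()
    catalog = load_catalog()
    files: list[Path] = []
    warnings: list[str] = []

    volume_table, dependency, _, _ = _uniform_stage(config, model, out, files, warnings)
    revolver_table, cov = _revolver_stage(config, model, out, files, warnings)

    flags = rb.repeatability_flags(cov, config.cov_threshold)
    labels = {f: (dependency.loc[f, "label"]
                  if dependency.loc[f, "label"] != "unevaluable" else "random")
              for f in catalog.features}
    fails = {f: bool(flags.loc[f, "fail"]) for f in catalog.features}
    keep = rb.load_reference_tables(catalog).keep_set(config.radionuclide)
    reduction = rb.reduce_features(catalog, labels, fails, keep_exceptions=keep)

    config.to_yaml(out / "config.yaml"); files.append(out / "config.yaml")
    _write_csv(volume_table, out / "features_volume.csv")
    files.append(out / "features_volume.csv")
    _write_csv(dependency, out / "dependency.csv"); files.append(out / "dependency.csv")
    _write_csv(revolver_table, out / "features_revolver.csv")
    files.append(out / "features_revolver.csv")
    _write_csv(cov, out / "cov.csv"); files.append(out / "cov.csv")
    reduction_json = {
        "radionuclide": config.radionuclide,
        "retained": reduction.retained,
        "n_retained": reduction.n_retained,
        "excluded_by": {f: reduction.table.loc[f, "excluded_by"]
                        for f in catalog.features},
        "keep_list_exceptions": sorted(
            reduction.table.index[reduction.table["keep_list_exception"]]),
        "warnings": warnings,
    }
    (out / "reduction.json").write_text(json.dumps(reduction_json, indent=1))
    files.append(out / "reduction.json")

    if config.make_plots:
        _plot_volume_curves(volume_table, out, files)

    manifest = {
        "radionuclide": config.radionuclide,
        "seed": config.seed,
        "files": {p.name: _sha256(p) for p in sorted(files)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return ReportBundle(config=config, volume_table=volume_table,
                        dependency=dependency, revolver_table=revolver_table,
                        cov=cov, reduction=reduction, manifest=manifest,
                        warnings=warnings)


def cov_screen_majority(radionuclide: str, seed: int = 0, n_blocks: int = 5,
                        voxel: float = 1.95) -> pd.DataFrame:
    """Run the Revolver repeat protocol ``n_blocks`` times (independent
    four-scan blocks) and vote: a feature counts as CoV-failing when it fails
    the 10% screen in a majority of blocks.

    Returns a per-feature frame with ``n_failing_blocks`` and ``fail``;
    steadier than a single four-scan experiment for noisy profiles whose
    feature CoVs sit near the threshold.
    """
    catalog = load_catalog()
    model = phantoms.IMAGING_DEFAULTS[radionuclide]
    votes = pd.Series(0, index=list(catalog.features))
    block_fail = {b: set() for b in range(n_blocks)}
    for k, syr_ml in enumerate((2.5, 5.0, 10.0)):
        geom = phantoms.PhantomGeometry.revolver(syr_ml)
        spec = phantoms.ActivitySpec.revolver(
            phantoms.REVOLVER_BACKGROUND_MBQ[radionuclide], geom)
        insert_model = dataclasses.replace(model, seed=seed + 1000 * (k + 1))
        scans = phantoms.generate_repeat_series(geom, spec, insert_model,
                                                4 * n_blocks, voxel)
        search = rasterize_sphere(geom.insert_center, 100.0, scans[0])
        params = SegmentationParams("percent_max", 0.40, search_region=search)
        rows = []
        for scan in scans:
            mask = segment(scan, params, geom.insert_center)
            vec = extract_all(scan, mask, catalog=catalog)
            rows.append({f: vec.values[f] for f in catalog.features})
        table = pd.DataFrame(rows)
        for b in range(n_blocks):
            cov = rb.cov_table({"block": table.iloc[4 * b:4 * b + 4]})
            flags = rb.repeatability_flags(cov)
            block_fail[b] |= set(flags.index[flags["fail"]])
    for b in range(n_blocks):
        votes[list(block_fail[b])] += 1
    return pd.DataFrame({"n_failing_blocks": votes,
                         "fail": votes > n_blocks / 2})


def validate_against_tables() -> dict:
    """Replay the published screens from their transcriptions and report the
    retained counts, the set differences against the transcribed retained
    lists, and every transcription inconsistency found on the way."""
    catalog = load_catalog()
    tables = rb.load_reference_tables(catalog)
    report: dict = {"catalog_size": len(catalog), "radionuclides": {}}
    for rn in ("tc99m", "lu177"):
        res = rb.replay_reduction(rn, catalog, tables)
        transcribed = tables.retained[rn]
        cov_feats = [e["feature"] for e in tables.cov_failures[rn]]
        duplicates = sorted({f for f in cov_feats if cov_feats.count(f) > 1})
        vol, cov = tables.exclusions(rn)
        report["radionuclides"][rn] = {
            "n_retained_replayed": res.n_retained,
            "n_retained_transcribed": len(transcribed),
            "replay_minus_transcribed": sorted(set(res.retained) - set(transcribed)),
            "transcribed_minus_replay": sorted(set(transcribed) - set(res.retained)),
            "n_volume_dependent": len(vol),
            "n_cov_failures": len(cov),
            "cov_table_duplicate_listings": duplicates,
            "keep_exceptions": sorted(tables.keep_set(rn)),
        }
    return report
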