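# spectomics

Phantom-based robustness screening of texture (radiomic) features for
quantitative SPECT.

Texture features extracted from 99mTc or 177Lu SPECT images are candidates
for clinical biomarkers, but many are unstable: their values track VOI
volume rather than tissue texture, or they fail to reproduce between
consecutive scans of the same object.  Nuclear-medicine radiomics
guidelines recommend two inexpensive phantom experiments to screen features
per centre before any clinical use:

1. **Volume dependency** — a uniform cylindrical phantom probed with 29
   concentric spherical VOIs (10–122 mm diameter).  A usable feature's
   curve f(V) must *converge* above small volumes; curves that keep
   trending with volume, or scatter randomly, flag the feature.
2. **Repeatability** — a "Revolver" insert (seven syringes at 4:1/8:1/16:1
   syringe:background activity ratios, emulating an inhomogeneous lesion)
   scanned four consecutive times; a feature fails if its coefficient of
   variation across the four scans, CoV = 100·σ/|μ|, exceeds 10% for any
   insert size (2.5/5/10 ml syringes).

`spectomics` implements the whole protocol as code: digital phantoms with
an image-domain SPECT model (Gaussian PSF + Poisson counts, per-radionuclide
profiles for 99mTc-LEHR and 177Lu-MEGP), a 67-feature IBSI-style texture
engine with fixed-bin-width SUV discretisation (64 bins over 0–20 SUV),
both VOI schemes, the two screens, and the combined feature reduction
`retained = catalogue − (non-converging ∪ CoV-failing) + keep-exceptions`.
The package also ships machine-readable transcriptions of the published
screen outcomes for both radionuclides, so the published reduction (39
features retained for 99mTc, 33 for 177Lu) can be replayed and audited.

## Worked example

```python
from spectomics.pipeline import RunConfig, run_experiment

cfg = RunConfig(radionuclide="tc99m", seed=1, out_dir="results/demo")
bundle = run_experiment(cfg)

labels = bundle.dependency["label"].value_counts().to_dict()
n_fail = int(bundle.cov.gt(10).any(axis=1).sum())
print(f"volume table: {len(bundle.volume_table)} VOIs x 67 features")
print(f"dependency labels: {labels}")
print(f"features with CoV > 10% in any insert: {n_fail}")
print(f"retained after reduction: {bundle.reduction.n_retained} / 67")
row = bundle.volume_table.iloc[-1]
print(f"largest VOI ({row['volume_ml']:.1f} ml): SUVmean = {row['SUVmean']:.3f}, "
      f"GLCM entropy log2 = {row['GLCM entropy log2']:.3f}")
```

prints

```
volume table: 29 VOIs x 67 features
dependency labels: {'converging': 32, 'correlated': 24, 'random': 11}
features with CoV > 10% in any insert: 7
retained after reduction: 30 / 67
largest VOI (949.6 ml): SUVmean = 1.000, GLCM entropy log2 = 2.284
```

Reading the output: the simulated uniform phantom reads SUVmean = 1.000 by
construction (SUV normalises concentration by activity per phantom mass).
32 features converge with volume; 24 trend monotonically and 11 scatter —
those 35 are volume-suspect.  7 features fail the 10% repeatability screen
in at least one Revolver insert under the 99mTc noise profile, and the
combined reduction keeps 30 of the 67.  One run writes `features_volume.csv`
(29×67), `dependency.csv`, `features_revolver.csv` (3 inserts × 4 scans),
`cov.csv`, `reduction.json` and a SHA-256 `manifest.json`; rerunning the
same config reproduces the manifest bit for bit.

A command-line interface wraps the same library:

```bash
spectomics simulate --phantom revolver --radionuclide lu177 --syringe-ml 5 \
    --repeats 4 --seed 1 --out scans/
spectomics segment --method percentmax --factor 0.4 --in scans/revolver_lu177_rep0.nii.gz \
    --out mask.nii.gz
spectomics extract --image scans/revolver_lu177_rep0.nii.gz --mask mask.nii.gz \
    --bins 64 --range 0,20 --out features.csv
spectomics run --config run.yaml
spectomics validate
```

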