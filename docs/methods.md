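# Methods

## What the package models

Radiomic (texture) features are only usable in clinical SPECT studies if
they are repeatable under re-scanning and not mere surrogates of lesion
volume.  Recent nuclear-medicine radiomics guidelines propose two cheap
phantom experiments to screen features per centre: a **uniform cylindrical
phantom**, probed with spherical VOIs of growing diameter, to expose volume
dependency; and a **"Revolver" insert** — seven syringes bound in a circular
bundle and filled at graded syringe-to-background activity ratios — placed
in a NEMA-IQ-style body and scanned repeatedly, to expose poor test–retest
repeatability in an inhomogeneous "lesion".  This package implements both
experiments end to end as simulations, plus the 67-feature texture engine
and the two screening rules, for the two radionuclides of interest in
quantitative SPECT: 99mTc (LEHR collimation) and 177Lu (MEGP collimation).

## Phantom geometry and activity

* Uniform cylinder: height 200 mm, diameter 220 mm, stated fill volume
  6244 ml, total activity 278 MBq (99mTc) or 670 MBq (177Lu).  The nominal
  outer dimensions enclose 7602 ml; the *fill volume* is authoritative for
  the activity concentration (total/fill) and the SUV mass, while the shape
  is rendered at nominal dimensions.  The grid integral of activity
  therefore exceeds the nominal total by the volume ratio; what the
  simulator guarantees is interior concentration (278 MBq/6244 ml =
  44.52 kBq/ml) and a rasterisation error below 2% against the analytic
  cylinder integral at 1.95 mm voxels.
* Revolver body: elliptical cylinder with half-axes 147 × 110 mm, length
  180 mm (a NEMA-IQ-like body).  Its fill volume is *derived* from the
  rendered geometry (π·a·b·L − 7 syringes ≈ 9.1 l) so activity/mass balance
  closes exactly; background activity 472 MBq (99mTc) or 386 MBq (177Lu).
* Syringes: barrels are cylinders of inner diameter 10/12/16 mm for
  2.5/5/10 ml nominal volumes (typical syringe barrels; the source protocol
  gives no dimensions), length set by volume, axes along the body's long
  axis, centre syringe plus six hexagonally packed ring syringes with
  touching barrels.
* Activity ratios: syringe:background concentrations use the stated set
  {4, 8, 16}.  Which barrel holds which ratio is not recoverable from the
  protocol figure; the default arrangement is 16:1 in the centre and the
  ring alternating 4:1/8:1, exposed as configuration.  Note that threshold
  segmentation outcomes depend on this choice: at 40% of SUVmax the 4:1
  barrels of the 2.5 ml insert fall below threshold at SPECT resolution,
  while the adaptive 2.5×background threshold captures all seven.

## Imaging model

No projector or reconstruction is simulated.  A quantitative SPECT scan is
abstracted as, in order: convolution with an isotropic Gaussian PSF;
scaling to expected counts (``count_scale`` = counts per kBq/ml per voxel);
Poisson sampling; rescaling to concentration; SUV calibration
(SUV = concentration × phantom mass / total activity, so a uniform phantom
reads SUV ≈ 1).  Per-radionuclide defaults:

| profile | PSF FWHM | count_scale | uniform-phantom voxel CoV |
|---------|----------|-------------|---------------------------|
| tc99m   | 8 mm     | 1.099       | ≈ 14.3%                   |
| lu177   | 12 mm    | 0.2284      | ≈ 20.2%                   |

The count scales are fixed by the closed form CoV = 1/√(count_scale ×
concentration) at each radionuclide's uniform-phantom loading, reproducing
the reported noise ordering of the two collimator/isotope combinations;
the PSF widths follow the LEHR/MEGP resolution ordering.  Every stochastic
operation takes an explicit seed; a repeat series uses seed, seed+1, …

What this surrogate does *not* emulate: reconstruction noise correlations
(Poisson sampling happens after the blur, so voxel noise is white),
scatter/attenuation residuals, dead time, and calibration drift.
Consequently the *membership* of the published screening tables is not
expected to be reproduced — only the structural properties: the noisier
profile fails more features, partial-volume effects inflate segmented
volumes, small-VOI texture features drift with volume.

## Feature catalogue and discretisation

Features follow the IBSI-style definitions with LIFEx v6.3 naming, 67 names
in eight families: 13 conventional SUV statistics (min/mean/std/max,
quartiles, population skewness/kurtosis/excess kurtosis, SUVpeak in 0.5 and
1.0 ml spheres, TLSRE = SUVmean × volume), 12 discretised counterparts
(computed on bin-centre values; sample skewness/kurtosis), 6 histogram
descriptors (population moments of the level distribution, entropies in
log2 and log10, energy), 4 shape features, GLCM ×7, GLRLM ×11, NGLDM ×3,
GLZLM ×11.  The published tables spell a discretised excess kurtosis two
ways; the catalogue carries it once (under the histogram family) and
normalises the alias, which is exactly what makes the published retained
counts (39 and 33) reproduce from the published exclusions — the shipped
consistency report surfaces the duplicate listings rather than hiding them.

Discretisation is fixed-bin-width: 64 bins over SUV 0–20, bin width
0.3125 SUV (reported rounded as 0.3), ``level = floor((x−0)/w)+1`` clamped
to [1, 64].

Texture conventions: distance-1 co-occurrences and runs are pooled over the
13 unique 3D directions *before* normalisation (merged strategy, as in
LIFEx; per-direction averaging is the main alternative).  Zones use
26-connectivity.  NGLDM uses the 26-neighbourhood restricted to the mask;
coarseness is capped at 1e6 on uniform regions.  Run percentage divides by
voxels × directions; zone percentage by voxels.  Features undefined on a
degenerate region (constant intensity → skewness; single grey level → GLCM
correlation) are flagged NaN and propagate to the screens as "unevaluable",
never as zeros.

Surface area comes from a marching-cubes mesh of the binary mask (voxel
faces for a single voxel).  For voxelised balls this mesh overestimates the
smooth-surface area by ~8%, so the sphericity of the sphere series plateaus
near 0.92 rather than 1; pre-smoothing the mask would move the plateau to 1
at the cost of unphysical sphericities > 1 for small spheres, so the
standard binary-mesh convention is kept and documented.

## VOI schemes

Volume dependency uses 29 concentric spheres, diameters 10–122 mm in 4 mm
steps (≈0.4–950 ml), voxelised by centre inclusion, all inside the phantom.
Revolver VOIs are threshold segmentations: 40% of SUVmax within a 100 mm
search sphere (default, matching how the published VOI volumes were made),
or 2.5× the mean of a 30 mm background sphere (the guideline method); in
both cases the VOI is the 26-connected supra-threshold component containing
the insert centroid, which makes the pipeline operator-free.

## Screening rules

* **Repeatability**: CoV = 100 × sample SD / |mean| across the four repeat
  scans, per feature and insert; a feature fails if CoV > 10% in any
  insert.  Degenerate values are dropped from the CoV; a feature with fewer
  than two valid repeats in every insert is unevaluable.  For stochastic
  comparisons between radionuclide profiles the package also provides a
  majority vote over five independent four-scan blocks, which is steadier
  when feature CoVs sit near the threshold.
* **Volume dependency**: the published protocol classified the 29-point
  curves *visually* into converging / correlated / random.  Reproducibility
  demands an algorithmic stand-in, so the classifier uses a tail-stability
  rule: a curve converges if every value at volumes ≥ 25 ml (the volume
  below which converging features were observed to vary) lies within 10% of
  the whole-curve range of the tail median; otherwise it is correlated if
  the tail's Spearman |ρ| ≥ 0.8, else random.  All three parameters
  (25 ml, 0.10, 0.8) are configuration, not constants.
* **Reduction**: excluded = non-converging ∪ CoV-failing, minus an explicit
  keep-exception list (features with established clinical value that are
  intentionally volume- or noise-tolerant, e.g. SUV statistics and shape).
  The default exception lists are shipped as data with per-feature
  provenance notes, derived from the published tables themselves: empty for
  99mTc; {SUVmin, NGLDM Contrast, GLZLM ZP} for 177Lu.

## Numerical and design choices

* Quartiles use linear interpolation (NumPy default); SUV std is the
  population estimator, CoV uses the sample (n−1) estimator — conventional
  for 4-repeat test–retest data.
* Kurtosis is the raw fourth standardised moment; excess kurtosis is
  kurtosis − 3; both appear in the catalogue where the tables name them.
* SUVpeak spheres are centred on every in-mask voxel and may extend past
  the mask but not past the image (normalised kernel average).
* Texture matrices are computed on the mask's bounding box (plus one voxel
  of padding), which, together with kernel-based peaks, makes every feature
  invariant to whole-voxel translations.
* The pipeline writes CSV/JSON outputs with fixed float formatting and
  records a SHA-256 manifest; a rerun from the same config is bit-identical.
* Problem sizes: all defaults run at the protocol's 1.95 mm voxels (the
  uniform phantom grid is 134×134×124).  The test suite's end-to-end cases
  use 3.9 mm voxels — the protocol is unchanged, only the grid is coarser —
  while the acceptance checks run at full resolution.

## Known limitations

* Image-domain noise is white; reconstructed SPECT noise is spatially
  correlated.  This mainly affects which *individual* features sit near the
  10% CoV threshold.
* The published screen memberships (which exact features failed) are
  camera- and reconstruction-specific and are treated as transcription
  data, not as simulation targets; the simulation reproduces the screens'
  structure, not their exact membership.
* Insert-count columns of the published CoV tables could not be recovered
  unambiguously from the flattened source tables; the transcriptions mark
  those assignments as layout-inferred, and only the union membership is
  used for the replay.
* Decay over the four consecutive scans is not modelled (activity held
  fixed per scan), consistent with scan times short against both isotopes'
  half-lives.
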