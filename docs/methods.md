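# Methods

## Scope and data model

All per-patient arrays (CT, dose, perfusion, lung and GTV masks) live on a
common voxel grid with physical spacing and origin in mm; dose and
perfusion are resampled to the CT grid (trilinear for scalars, nearest for
labels) before any feature computation. Dose is stored in absolute Gy;
%-of-prescription quantities are derived on demand. Volumes are read and
written as NIfTI or NRRD through SimpleITK; feature tables are CSV with 12
significant digits.

## Functional regions

The perfusion map is normalized by `(f - min)/(max - min)` with min/max
taken over **lung voxels only**, so the lung range is exactly [0, 1]; the
normalization is idempotent. The protocol wording for the denominator is
ambiguous ("divided by the maximum"); dividing by the range is the only
reading that produces the stated 0-1 range, and is what we implement.
Voxels exactly at the threshold are assigned to the HIGH region (>=
convention); the threshold default is 0.3 and is sweepable (0.2-0.8). The
GTV is excluded from WL, high and low alike, and (high, low) is an exact
partition of WL by construction.

## Radiomics engine

Feature definitions follow the standard reference formulas used across
radiomics software (IBSI-style). The intensity catalog per (image type,
bin count) is 91 features: 18 first-order, 22 GLCM, 16 GLRLM, 16 GLSZM, 14
GLDM, 5 NGTDM. Conventions that matter:

- **Discretisation**: fixed bin count, equal-width bins over the ROI
  [min, max]; the maximum closes into the top bin; a constant ROI maps to
  a single level. Fixed-bin-count makes texture features invariant to
  intensity shifts and scalings (tested).
- **Texture aggregation**: 3D, 26-connectivity. GLCM and GLRLM are built
  per angle (13 unique directions, symmetric GLCM) and feature values are
  averaged over angles. Gray levels entering the formulas are the actual
  discretised values present in the ROI; zero rows/columns are dropped
  from normalization. Degenerate cases (single level, single voxel) yield
  the natural limits (entropy 0, correlation 1, NGTDM coarseness capped at
  1e6) rather than errors.
- **Filter bank**: original + 8 level-1 stationary-wavelet sub-bands
  (coif1; odd axes reflect-padded), Laplacian-of-Gaussian (sigma = 1
  voxel), square and square-root of min-shifted intensities. The bank size
  (12 image types) is the normative constraint; the membership is this
  package's choice and is configurable. With 5 bin counts the catalog is
  12 x 5 x 91 + 14 shape = 5,474 per ROI.
- **Shape**: mesh-based volume/area from marching cubes at the 0.5
  iso-level after smoothing the padded binary mask with a sigma = 0.8
  voxel Gaussian. The smoothing anti-aliases the staircase surface (a raw
  binary mesh overestimates a digital ball's area by ~9%, which would
  push sphericity to 0.91; with smoothing the ball measures within 1-3% of
  the analytic sphere). ROIs too thin to survive smoothing fall back to
  the unsmoothed mesh; ROIs under 4 voxels use voxel-count fallbacks.
  Axis lengths are 4*sqrt(eigenvalue) of the physical-coordinate
  covariance; 2D diameters are per-plane convex-hull diameters.

## Dose features

- **DVH**: Dx = minimum dose to the hottest x% volume, linearly
  interpolated on the cumulative volume grid; Vx = % of ROI volume
  receiving >= x Gy or >= x% of prescription. The default 59-entry catalog
  is D2, D5..D95 (step 5), D98 (21), V5..V70 Gy (14), V5..V120 %Rx (24);
  only the total is normative upstream, the list is configurable and the
  59-count invariant is checked against the configured catalog.
- **Spatial moments**: central moments of the dose-weighted voxel-position
  distribution in world mm, normalized as
  `eta_pqr = mu_pqr / mu_000^(1+(p+q+r)/3)` over all (p,q,r) in {0..3}^3
  except (0,0,0) — 63 values. The weights include the voxel volume
  (`w = D dV`), i.e. the moments are the continuous integrals'
  Riemann sums; this is what makes eta exactly invariant under uniform
  spatial rescaling (verified to 1e-9 relative).
- **Dosiomics**: the 91 intensity features on the raw dose grid, original
  image type only, bin count 50 (one setting; the value is this package's
  default since only the feature count is normative).

Total: 63 + 59 + 91 = 213 per region.

## Feature selection

100 stratified 70% subsamples (stratification guarantees both outcome
classes in every draw; it can be switched off). Per subsample,
zero-variance features are dropped and a two-group ANOVA F-test with
(1, n-2) df marks features with p < 0.01. Frequencies are mark sums. The
top `max(ceil(0.10 N), 40)` features (N = non-constant feature count,
capped at N) are reserved in frequency order — ties broken by mean F
statistic, then name, making the outcome invariant to column order. A
greedy frequency-ordered Pearson scan keeps a feature iff |r| <= 0.5
against everything already kept.

## Modeling and evaluation

30 stratified splits; per class floor(n/4) patients go to test (126
patients with a 64/62 outcome split give test cohorts of 31). Selection
runs on each training cohort. The ridge classifier solves the penalized
least-squares problem on z-scored features (train statistics only) and
+/-1 labels via SVD; alpha is picked from a log grid by 10-fold
stratified CV maximizing the AUC of the continuous decision value.

The feature-count sweep evaluates k = 1..K (K = largest per-split primary
group, optionally capped). Two modes:

- `paper-faithful`: k* maximizes the across-split mean **testing** AUC.
  This reproduces the protocol under study; it lets the test cohorts
  inform one hyperparameter, which is why the suite includes a
  permuted-label calibration check showing the resulting optimism stays
  within the Monte-Carlo noise band at this cohort size.
- `honest-nested` (default for new analyses): k* maximizes the inner
  cross-validated AUC of the training folds only.

The "final optimal feature group" across splits is the top-k* features by
cross-split selection frequency (the aggregation rule is this package's
choice), with weights refit on the full cohort. Reported statistics:
mean +/- SD of AUC/accuracy/precision/recall/F1 over splits in train and
test; a 95% CI over splits and a DeLong CI (with a 2,000-replicate
bootstrap CI as a secondary output) on the pooled test scores; paired
two-sided t-tests between feature sets; chi-square (no continuity
correction) for categorical and two-sample t for continuous cohort
covariates; decision curves with net benefit
`NB(pt) = TP/n - FP/n * pt/(1-pt)` against treat-all/treat-none, with
decision values mapped to probabilities by logistic calibration on
training scores.

## Synthetic cohort generator

The generator emulates the *statistical* structure the analysis assumes,
not anatomy: two-ellipsoid lungs, a spherical GTV excluded from the lung,
an anisotropic Gaussian dose bath whose GTV-centre voxel equals the
prescription (drawn uniformly in 50-70 Gy), a smooth positive log-normal
perfusion field (correlation length 15 mm) with a hypo-perfused ellipsoid
ensuring both functional classes exist at threshold 0.3, and CT as
tissue/air base values plus noise. Defaults: 126 patients, 48^3 grid at
3 mm, target RP prevalence 0.508. Covariates are drawn to match the
reference cohort's marginals (86.5% male, age ~61, stage IIIA/B/C
0.57/0.29/0.14, ...).

The RP label is Bernoulli with logit
`beta0 + 2.0 z(meanDose(high)) + 0.5 z(doseSD(low)) + eps`,
`eps ~ N(0, 0.4)`; the standardization constants are the generator's
nominal feature scales and `beta0` is calibrated per cohort so the
expected prevalence hits the target. The planted features are exactly two
columns of the extracted FWL dose table
(`highFWL:D:dosio:firstorder:Mean`, `lowFWL:D:dosio:firstorder:Variance`),
so recovery tests can ask whether the pipeline finds them.

What passing tests on phantoms does **not** show: performance on real
patients. The phantoms have no respiratory motion, no contouring noise,
no scanner effects, smooth unimodal dose baths, and a planted low-rank
outcome mechanism; absolute AUCs on phantoms are not comparable to
clinical values, only directional contrasts (FWL vs WL) and calibration
properties are meaningful.

## Problem sizes used in the shipped checks

The package's own verification runs at desk scale: full-catalog extraction
(5,474 + 213 features) on single 48^3 phantoms; cohort-level experiments
on 126 phantoms with the reduced extraction settings (original image type,
bin count 50 — 105 radiomics + 213 dose features per region), 30 splits,
50-repeat selection, a 9-point alpha grid and the sweep capped at k = 15.
All algorithms are resolution- and catalog-size-agnostic; the full
settings are the defaults for real analyses.

## Numerical choices and degenerate inputs

- Empty ROI -> `DegenerateROIError`; constant perfusion over the lung ->
  `DegeneratePerfusionError`; zero total dose -> `ZeroDoseError`.
- An empty high or low region at an extreme threshold is a warning at
  segmentation time and an error only when features are requested for it.
- Single-class subsample draws are redrawn (>10 consecutive failures is a
  configuration error); stratification makes them impossible by default.
- Ridge alpha ties resolve to the larger alpha; reservation ties resolve
  by mean F then name; all randomness flows from explicit integer seeds
  (master seed -> split seeds -> selection seeds -> bootstrap seeds).

## Known limitations

- The filter-bank membership, the 59 DVH specs, the dosiomics bin count
  and the cross-split aggregation rule are documented package choices;
  upstream only the counts/totals are fixed.
- The sampled LoG kernel leaves a ~2e-4 relative DC residual on constant
  images (it is not exactly zero-sum).
- Mesh smoothing slightly erodes sub-centimetre ROIs; their mesh volume
  under-reads relative to the voxel count.
- DICOM-RT structure rasterization is out of scope; masks must arrive as
  label volumes.
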