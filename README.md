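# fwlomics

Function-wise dual-omics analysis for radiation-pneumonitis (RP) risk
modeling in thoracic radiotherapy.

## The problem

Radiation pneumonitis is the dose-limiting lung toxicity of thoracic
radiotherapy. Classical predictors use whole-lung dose-volume metrics and
ignore that lung function is spatially heterogeneous: irradiating a
well-perfused region is plausibly more harmful than irradiating an already
hypo-perfused one. `fwlomics` implements a *function-wise* analysis: the
lung is split into high- and low-functional sub-regions by thresholding a
normalized perfusion map, and radiomics plus dose features extracted from
those sub-regions are compared against whole-lung features as predictors of
grade >= 2 RP.

The package is aimed at radiotherapy outcome-modeling researchers. Real
perfusion maps (SPECT or synthesized) are inputs; a first-class synthetic
cohort generator provides phantoms with the assumed statistical structure
so the entire pipeline is testable without patient data.

## Method

Per patient, with planning CT, 3D dose (Gy), lung and GTV masks and a
perfusion map on a common grid:

1. **Functional regions** — perfusion is min-max normalized over lung
   voxels, `f' = (f - min) / (max - min)`, and thresholded at 0.3:
   high-functional lung `f' >= 0.3`, low-functional `f' < 0.3`. The GTV is
   excluded everywhere. WL = whole lung; FWL = the (high, low) pair.
2. **Radiomics** — per region-of-interest, 12 image types (original, 8
   stationary-wavelet sub-bands, Laplacian-of-Gaussian, square,
   square-root) x 5 bin counts (20/50/100/150/200) x 91 intensity features
   (18 first-order + GLCM 22 + GLRLM 16 + GLSZM 16 + GLDM 14 + NGTDM 5),
   plus 14 mesh-based shape features: **5,474 features**.
3. **Dose features** — 63 scale-invariant spatial dose moments
   `eta_pqr = mu_pqr / mu_000^(1+(p+q+r)/3)` for p,q,r in 0..3, 59 DVH
   parameters (Dx / Vx in Gy and % of prescription) and 91 dosiomics
   features on the raw dose grid: **213 features**.
4. **Feature selection** — 100 stratified 70% patient subsamples; per
   subsample a two-group ANOVA F-test marks features with p < 0.01;
   marks are summed into a selection frequency; the top
   `max(ceil(0.10 N), 40)` features are reserved, then greedily pruned so
   no kept pair has |Pearson r| > 0.5.
5. **Modeling** — 30 stratified 3:1 train/test splits; per split the
   selection runs on the training cohort; feature counts k = 1..K are
   swept; a ridge classifier (`min ||Xw - y||^2 + alpha ||w||^2`, labels
   +/-1, alpha by 10-fold cross-validated AUC) is fit per k. Six feature
   sets are compared (WL/FWL x radiomics/dose/both) with AUC, accuracy,
   precision, recall, F1, DeLong confidence intervals, paired t-tests,
   chi-square cohort tests and decision-curve analysis.

## Worked example

```python
import numpy as np
from fwlomics import (CohortConfig, generate_cohort, cohort_feature_tables,
                      cohort_labels, run_experiment, ExperimentConfig)
from fwlomics.radiomics.settings import REDUCED_SETTINGS

records, truth = generate_cohort(CohortConfig(seed=101))   # 126 phantoms
tables = cohort_feature_tables(records, 0.3, REDUCED_SETTINGS)
report = run_experiment(tables, cohort_labels(records).to_numpy(),
                        ExperimentConfig(seed=101, mode="paper-faithful"),
                        feature_sets=("WL-RD", "FWL-RD"))
for name, m in report.models.items():
    mu, sd = m.summary["test_auc"]
    print(f"{name}: mean test AUC {mu:.3f} +/- {sd:.3f} (k*={m.chosen_k})")
```

Output from this exact script:

```
WL-RD: mean test AUC 0.537 +/- 0.104 (k*=7)
FWL-RD: mean test AUC 0.750 +/- 0.086 (k*=1)
```

The phantom cohort plants the RP signal in the dose delivered to the
high-functional region, so the function-wise model (FWL-RD) separates
cases markedly better than the whole-lung model (WL-RD) — the qualitative
contrast the analysis is designed to expose. Absolute AUCs depend on the
generator's noise settings and seed.

The same pipeline is available from the shell:

```bash
fwlomics synth-cohort --n 126 --seed 7 --out cohort/
fwlomics run --n 126 --seed 7 --out report/
```

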