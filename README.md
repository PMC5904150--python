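# dkitex

Texture-analysis and SVM pipeline for **diffusional kurtosis imaging
(DKI)** radiomics, aimed at small-cohort glioma studies: grading
(WHO 2 vs 3) and IDH-mutation phenotyping from mean-diffusional-kurtosis
(MDK) and FLAIR images.

The pipeline chains four stages, each usable on its own:

1. **Kurtosis model fitting** (`dkitex.dki`) — per voxel and gradient
   direction, fit `S(b) = S0·exp(−b·D + (1/6)·b²·D²·K)` by linear least
   squares in log-signal space; the MDK map averages `K̂` over the 30
   directions of the six-shell (0–2800 s/mm²) scheme.
2. **MR8 texture channels** (`dkitex.mr8`) — the 38-filter
   maximum-response bank (Gaussian, LoG, 18 edge + 18 bar filters at 3
   scales × 6 orientations) reduced to 8 rotation-invariant channels
   plus raw intensity.
3. **Biomarker extraction** (`dkitex.biomarkers`) — per tumor VOI and
   modality, 9 channels × 6 statistics (mean, median, SD, kurtosis,
   p5, p95) = the canonical 54-element, 1-based-indexed biomarker
   vector.
4. **Classification and selection** (`dkitex.classification`,
   `dkitex.rfe`) — class-weighted RBF-SVM with Platt-calibrated
   probabilities under nested leave-one-out cross-validation; biomarker
   panels chosen by kernel-RFE frequency voting (survivors at
   N ∈ {4,5,6} pooled over outer folds, top four win).

Because cohorts of this kind are not public, `dkitex.synthetic`
generates every input with known ground truth — kurtosis-model DWI
decays with Rician noise, two-class Gaussian-random-field texture
phantoms with spherical VOIs, and tabular feature sets with planted
informative columns — so the whole chain is testable end to end.  See
`docs/methods.md` for the models, conventions, and design decisions.

## Worked example

A 37-subject two-class phantom cohort (26 vs 11) in which only the
MDK-like channel carries a class difference (lower mean kurtosis in
class 0), pushed through the full study (runs in ~1 minute):

```python
from dkitex import PhantomSpec, generate_phantom_cohort, run_full_study
from dkitex.classification import SMALL_C_GRID, SMALL_GAMMA_GRID, SvmConfig
from dkitex.pipeline import extract_feature_table

spec = PhantomSpec(grid_shape=(48, 48, 10), n_subjects_per_class=(26, 11),
                   voi_radius=8.0, voi_radius_jitter=1.0, seed=11)
table = extract_feature_table(cohort=generate_phantom_cohort(spec))
cfg = SvmConfig(c_grid=SMALL_C_GRID, gamma_grid=SMALL_GAMMA_GRID, seed=0)
report = run_full_study(table, svm_config=cfg, task="idh")
```

which prints (formatted):

```
first-order: acc 0.811  consistently selected: ['mean', 'median', 'p5', 'p95']
dki   acc 0.784  sens 0.64  spec 0.85  AUC 0.829
flair acc 0.676  sens 0.00  spec 0.96  AUC 0.126
both  acc 0.784  sens 0.64  spec 0.85  AUC 0.892
DKI vs FLAIR AUC p-value: 0.000
RFE top-4 biomarkers: [1, 8, 11, 2]
  - mean of intensity
  - median of Gaussian filter response
  - p5 of Gaussian filter response
  - median of intensity
selected-4 metrics: acc 0.865 AUC 0.923
```

Reading this: the ANOVA-filtered first-order experiment consistently
picks the four location statistics (the planted signal is a mean shift,
so spread/shape statistics carry nothing); the DKI texture biomarkers
separate the classes (accuracy 78%, AUC 0.83) while the FLAIR channel —
identical across classes by construction — cannot beat predicting the
majority class; RFE voting lands on intensity/Gaussian location
biomarkers, which is exactly where the planted signal lives, and the
four of them classify at least as well as all 54.  LOOCV metrics at
n = 37 remain noisy; the test suite repeats these experiments over many
seeds.

A command-line interface wraps the same stages for file-based work
(NIfTI volumes + cohort CSV):

```bash
dkitex simulate --out cohort/ --seed 1
dkitex extract  --cohort cohort/cohort.csv --out features.csv
dkitex classify --features features.csv --feature-set dki --out runs/
dkitex select   --features features.csv --out top4.json
dkitex study    --features features.csv --task idh --out study/
```

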