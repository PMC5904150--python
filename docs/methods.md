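# Methods

`dkitex` re-implements, as a tested library, a radiomics pipeline for
glioma characterisation from diffusional kurtosis imaging (DKI): fit the
kurtosis signal model per voxel, summarise tumor texture through the MR8
maximum-response filter bank, classify subjects with a class-weighted
RBF-SVM under nested leave-one-out cross-validation (LOOCV), and select
a compact biomarker panel by SVM recursive feature elimination (RFE)
with frequency voting.  Because clinical DKI cohorts of this kind are
not public, every stage is exercised end-to-end on synthetic inputs with
known ground truth; this note records the models, the defaults, and the
design choices that were genuinely open.

## Kurtosis signal model

Per voxel and gradient direction the diffusion signal is modelled as

    S(b) = S0 · exp(−b·D + (1/6)·b²·D²·K)

with apparent diffusivity `D` (mm²/s) and apparent kurtosis `K`
(dimensionless).  The fit is deliberately isotropic (no kurtosis
tensor): each direction is fitted independently and the mean diffusional
kurtosis (MDK) map is the arithmetic mean of the per-direction `K̂`.
Taking logs makes the model linear in `(ln S0, D, β₂)` with
`β₂ = D²K/6`, so the fit is an ordinary least-squares solve followed by
the reconstruction `K = 6β₂/D²`.  This gives a unique, fast solution and
makes the noiseless generator→fitter round trip exact to machine
precision (verified to ≤1e−6 relative over `D ∈ [0.3, 3]×10⁻³`,
`K ∈ [0, 3]`).  Constraints are applied by projection: `D̂ ≥ 10⁻⁶` mm²/s
and `K̂` clipped to `[0, 3]`, a physically plausible brain range.  Voxels
with non-positive signal (log undefined) are flagged invalid, carried as
NaN, and excluded from all downstream VOI statistics.  The default
acquisition scheme is six shells `{0, 500, 1000, 1500, 2000, 2800}`
s/mm² with 30 directions.

Magnitude MR noise is Rician, so the synthetic DWI generator corrupts
the clean decay as `sqrt((S+ε₁)² + ε₂²)` with Gaussian `ε`.  This
matters at high b-value where SNR is low: the Rician floor biases the
fitted kurtosis, and the Monte-Carlo tests quantify that bias (≈ a few
percent at SNR 50) rather than assuming it away.

## MR8 filter bank

The bank holds 38 filters: Gaussian and Laplacian-of-Gaussian (σ = 1),
plus edge (first-derivative) and bar (second-derivative) anisotropic
Gaussian filters at scales `(σx, σy) ∈ {(3,1), (6,2), (12,4)}` and six
orientations `{0°, 30°, …, 150°}`.  Per scale and filter type the six
orientation responses collapse to one channel by taking a maximum,
giving 8 rotation-invariant channels; with raw intensity that makes 9
feature channels.

Numerical choices:

* **Kernels are pixel-integrated**: each kernel entry is the continuous
  filter averaged over the pixel area (5×5 sub-pixel sampling).  Point
  sampling leaves the σy = 1 kernels so coarsely represented that their
  frequency response differs by several percent across orientations,
  which visibly breaks rotation invariance at the finest scale.
* **Support and boundaries**: kernels truncate at ±3σ (odd size);
  slices are reflect-padded before filtering so responses near the VOI
  see plausible neighbourhood context rather than zeros.  Filtering is
  applied to the full slice and masked afterwards.
* **2D slicewise filtering**: the bank is two-dimensional and the
  targeted acquisitions have coarser slice spacing (2.5 mm) than
  in-plane resolution (~2 mm), so filtering is per axial slice.
* **Orientation reduction uses max |response|**.  An odd (edge) filter
  at orientation θ+180° is the negated filter; over a six-orientation
  set spanning [0°, 180°) the *signed* maximum is therefore not
  invariant under rotations that wrap orientations past 180° (measured
  KS distance up to ≈0.45 for 90° rotations), whereas the absolute
  maximum equals the signed maximum over the full 360° continuum and is
  exactly invariant under 90° rotations and invariant to KS ≤ 0.06
  under 30°/60° rotations of band-limited textures.  The signed
  reduction remains available (`abs_response=False`).
* Kernels are zero-mean (except the Gaussian) and L1-normalised; no
  image-level intensity normalisation is applied by default.

Rotation invariance is asserted distributionally: a band-limited test
pattern (multi-period grating plus smoothed noise) is rotated to two
angles 30° or 60° apart — both comparands interpolated once, so spline
attenuation cancels — and each max-response channel's distribution in a
central window must agree to KS ≤ 0.1.  Pure single-frequency sinusoids
are unsuitable probes: the perpendicular orientation's response is
exactly zero, which puts a point mass in the max-channel distribution
and makes the KS statistic degenerate.

## Biomarker vectors

For each of the 9 channels, six statistics over in-VOI voxels — mean,
median, SD, kurtosis, 5th and 95th percentile — give 54 biomarkers per
modality (DKI and FLAIR; concatenated 108 with DKI first).  The index
convention is channel-major and 1-based with channels ordered
[intensity, Gaussian, LoG, edge scales ascending, bar scales ascending]:
`index = (channel−1)·6 + statistic`.  The convention is pinned by seven anchor
(index, descriptor) pairs — e.g. 11 → p5 of the Gaussian response,
52 → kurtosis of the bar(12,4) response — that are frozen in the test
suite so the mapping can never drift silently.

Statistical conventions (configurable, defaults follow the dominant
statistical-software behaviour): SD uses the n−1 denominator, kurtosis
is bias-corrected excess kurtosis (normal = 0), skewness the adjusted
Fisher–Pearson coefficient, percentiles linear interpolation (type 7).
NaN voxels are dropped per channel; a VOI with fewer than 10 valid
voxels is an error.

## Classification protocol

Binary tasks (e.g. WHO grade 2 vs 3; IDH mutant vs wild-type) are
classified by a soft-margin RBF-SVM.  The estimation protocol is nested
LOOCV: the outer loop holds out one subject for assessment; the inner
loop — LOOCV over the remaining n−1 — picks `(C, γ)` from a grid by
accuracy, ties broken toward the smallest C then smallest γ (the
smoothest model).  The default grid is the libsvm-style
`C ∈ 2^{−5..15}`, `γ ∈ 2^{−15..3}` (steps of 2²); the simulation studies
in the tests and the acceptance script use a compact 5×5 sub-grid
(`C ∈ {2⁻³…2⁹}`, `γ ∈ {2⁻⁷…2}`), which keeps the many Monte-Carlo
replicates at interactive problem sizes.

Features are z-scored with training-fold statistics only; zero-variance
features are centred and left inert.  Class imbalance is handled by
per-class penalties `w_i = n/(2·n_i)`.  **The weights are computed once
per outer training fold and held fixed for every fit inside that
fold.**  This granularity matters: recomputing "balanced" weights inside
each inner leave-one-out fit ties the SVM's bias term to the one-subject
composition change, which leaks the inner held-out label — on pure-noise
data the degenerate small-(C, γ) grid cells then reach inner accuracy
≈1.0 and win the grid search.  With fold-fixed weights those cells score
at chance or below and the protocol's permuted-label accuracy sits
inside the binomial null band around the majority-class prior.

A residual caveat, documented rather than hidden: on *balanced* null
cohorts, leave-one-out protocols with fitted classifiers are
pessimistically biased (holding out a subject shifts its own class's
training distribution away from it), so null accuracy falls below 0.5
rather than above.  Leakage would manifest as optimism; the tests assert
the two-sided band at the imbalanced cohort structure the pipeline
targets (26:11) and treat the balanced-null pessimism as the known
property of LOOCV that it is.

Decision values are calibrated to probabilities by Platt scaling
(sigmoid `1/(1+exp(A·f+B))`, Newton optimisation with Platt's smoothed
targets), fitted on out-of-sample decision values from an internal
stratified 3-fold split of the training fold.  The reported operating
point is probability 0.5.  ROC/AUC uses the rank (Mann–Whitney)
formulation with half-credit ties; paired ROC curves are compared with
DeLong's test.  Group comparisons use Shapiro–Wilk, one-way ANOVA,
Kruskal–Wallis and chi-square as applicable, at significance 0.05.

The first-order experiment feeds the six MDK summary statistics to the
same machinery, but replaces the inner feature set by a per-fold one-way
ANOVA filter (keep p < 0.05 on the training subjects; if nothing passes,
the single smallest-p feature survives, and the event is recorded).

## RFE biomarker selection

With an RBF kernel there is no per-feature primal weight, so elimination
uses the standard kernel generalisation of weight-based RFE: with the
dual solution fixed, feature f's importance is the change in the margin
objective `(1/2)·aᵀKa` when f is removed from the kernel computation.
One feature is eliminated per iteration and the SVM refit; `(C, γ)` are
tuned once per fold (inner LOOCV on all features) and held fixed during
elimination — re-tuning at every step is combinatorially expensive and
changes nothing in the planted-truth recovery experiments.

The voting scheme runs the elimination inside every outer LOOCV fold,
records the survivor sets at N ∈ {4, 5, 6}, pools them, and ranks
features by selection frequency; the top four are the final panel.  Ties
break by better mean elimination rank, then lower index.  Note that the
voting protocol pools all outer folds and then re-evaluates the winning
panel on the same cohort — a mild optimism inherent to the design;
`evaluate_selected` reproduces that protocol, and a fully nested estimate can be obtained by
running the voting inside an additional outer loop.

## Synthetic data: what it emulates and what it does not

* **DWI decays** follow the kurtosis model exactly, with Rician noise —
  they validate the fitter (inverse crime) and its noise robustness, not
  scanner artefacts, motion, or eddy currents.
* **Texture phantoms** are stationary Gaussian random fields (white
  noise convolved with an isotropic Gaussian whose width is the class
  correlation length), with spherical VOIs (radius jittered per
  subject) on a 128×128×12 grid at (1.95, 1.95, 2.5) mm by default.
  Scalar values live on the a.u. scale of the targeted cohort's
  descriptive statistics: class mean MDK 521.8 vs 637.4 inside the VOI
  (the low-MDK class is class 0), subject-level SD 40, voxel-level SD
  60, background 350.  The FLAIR-like channel has identical class
  parameters by default, so any DKI-over-FLAIR ranking downstream is
  attributable to the planted MDK difference.  Real tumor shape,
  anatomy, registration error and multi-modal correlation are *not*
  emulated: passing tests show the pipeline recovers planted structure,
  not that it reproduces clinical accuracies.
* **Tabular cohorts** plant informative columns (class-mean shift in SD
  units) among standard-normal noise at the target cohort structure
  (n = 37, 26:11 by default) for selection-recovery experiments.

All generators are deterministic given their seed.

## Problem sizes

Simulation studies run at the cohort scale the pipeline targets
(n = 37, 54 biomarkers, 26:11 imbalance).  Monte-Carlo breadths are 20
label permutations, 10 separable-cohort seeds, and 30 selection-recovery
seeds; phantom cohorts for the modality comparison use 64×64×12 grids
(37 subjects), and the smoke-level cohort fixtures 48×48×10 with 14
subjects.  The inner grid search uses the compact 5×5 grid in these
studies.  These sizes were chosen so the full suite runs at interactive
speed; the library itself has no fixed problem size.

## Known limitations

* The per-direction scalar kurtosis fit ignores directional coupling; a
  full kurtosis tensor is out of scope by design.
* The log-domain least-squares fit weights residuals uniformly in
  log-signal, which slightly over-weights high-b (low SNR) samples; a
  weighted or nonlinear refinement pass would reduce the Rician bias at
  very low SNR.
* MR8 responses are computed slicewise; strongly anisotropic 3D texture
  is only captured in-plane.
* LOOCV metrics on small cohorts have high variance and the
  frequency-voting re-evaluation shares data between selection and
  assessment, as in the published protocol; treat the selected-panel
  metrics as comparative, not absolute.
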