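# Methods

This note documents the models, numerical choices and limitations behind
`ringomics`. It describes what the code computes and why the defaults are
what they are; every empirical number mentioned here is recomputed by the
test suite or by `scripts/acceptance.py`, never stored.

## 1. Geometry: the peritumoral ring

The tumor boundary is the set of tumor voxels with at least one 6-connected
background neighbour. Every voxel gets a signed Euclidean distance (in mm,
spacing-aware, via two distance transforms) to this boundary-voxel set,
negative inside the tumor. The peritumoral ring is the band

```
ring = { v : -inner_mm < sd(v) <= outer_mm } \ exclusion
```

with defaults `outer_mm = 2`, `inner_mm = 1`, i.e. a nominal 3 mm shell
straddling the boundary. Defining distance to boundary *voxel centres*
(rather than to a subvoxel interface) keeps the construction identical to a
brute-force per-voxel minimum-distance oracle, which the tests exploit; the
price is a half-voxel-scale widening of the measured band (on a 20 mm
sphere at 0.5 mm spacing the realized thickness is ~3.2 mm, within one
voxel diagonal of nominal).

The intratumoral ROI is the **full tumor mask**: nothing in the problem
definition indicates the tumor ROI is eroded by the ring's inner 1 mm, so
the 1 mm overlap between ring and tumor is intentional. Exclusion masks
(air below −500 HU, vessels/bone above +300 HU by default; both
config-exposed) are intensity rules only — true anatomical adjacency is out
of scope — and are applied to the ring, not to the tumor ROI.

Resampling to isotropic spacing uses trilinear interpolation for
intensities and nearest-neighbour for masks.

## 2. The 584-feature pool

Per region (intratumoral, peritumoral): 14 first-order intensity features,
8 shape features, and 45 texture features at each of 6 fixed bin counts
{8, 16, 32, 64, 128, 256}, for 292 per region and 584 per case. The exact
texture composition is a reconstruction: 24 GLCM + 16 GLRLM + 5 NGTDM = 45
divides 270 evenly over the 6 discretizations. The canonical GLCM list
contains 25 names, but `dissimilarity` coincides with `difference_average`
on a symmetric matrix, so the catalogue keeps 24 distinct features
(`glcm_features` still returns dissimilarity for callers). The catalogue is
config-overridable via `bin_counts`.

Numerical conventions:

* **Discretization** — fixed bin *count* over the ROI's [min, max]
  (robust to the synthetic HU ranges; bin-width discretization is not
  implemented). A constant ROI maps to level 1.
* **GLCM/GLRLM aggregation** — co-occurrences and runs over the 13 unique
  3D directions are merged into a single matrix before normalization
  ("merged" aggregation), giving one deterministic value per feature and
  invariance to 90° grid rotations on isotropic grids.
* **Degenerate ROIs** — skewness/kurtosis of a constant ROI are 0;
  GLCM correlation is 0 when a marginal variance vanishes;
  information-correlation features are 0 when the relevant entropies
  vanish; NGTDM coarseness is capped at 10⁶ for flat ROIs, and its
  busyness/strength denominators of 0 yield 0. Kurtosis is excess
  kurtosis; variance is the population variance. First-order entropy and
  uniformity use a fixed 64-bin discretization.
* **Shape** — volume is voxel count × voxel volume; surface area comes
  from a marching-cubes isosurface after light Gaussian anti-aliasing
  (σ = 0.8 voxel), which removes the voxel staircase that otherwise
  inflates smooth surfaces by ~8%; sphericity pairs that mesh area with
  the mesh-enclosed volume so a digital sphere scores ≈ 1 from below
  (the trade-off: strongly faceted shapes are slightly rounded). Maximum
  3D diameter uses convex-hull vertices; axis lengths are 4·√eigenvalue
  of the voxel-coordinate covariance, elongation √(λ₂/λ₁). Shape features
  are computed on both ROIs (ring included) for catalogue symmetry.
* No wavelet/LoG filtered features.

GLCM, GLRLM and NGTDM are verified against brute-force enumeration oracles
on all small grids (hypothesis sweep, ≤5³, ≤4 levels).

## 3. Signature construction

The training label is **NLR-High (1) vs NLR-Low (0)**; Mix cases do not
enter the fit (the High-vs-rest contrast is evaluation-only). Fitting is:

1. **mRMR pre-selection (k = 30)** — greedy FCD variant: relevance is the
   one-way ANOVA F-statistic of a feature against the label, redundancy the
   mean absolute Pearson correlation with already-selected features, score
   = relevance − redundancy. Deterministic; ties break in catalogue order.
   Because the F-statistic is unbounded while redundancy is ≤ 1, the
   redundancy term demotes duplicates only among comparably relevant
   features — accepted as the standard behaviour of this variant.
2. **LASSO logistic regression** on z-scored features, penalty chosen to
   minimize mean 5-fold cross-validated binomial deviance over a
   logarithmic λ grid (40 points, 10⁻³…10^1.5; the minimum-deviance rule,
   not 1-SE), folds stratified and seeded, refit at the chosen λ on all
   training data. An all-zero coefficient vector raises a
   `SignatureEmptyError` pointing at the λ grid.
3. **RS and groups** — RS = intercept + Σ coef × z-scored feature; tertile
   cutoffs are the empirical 1/3 and 2/3 quantiles of the training RS,
   with the boundary belonging to the lower group (RS ≤ q₁ → RS-Low).

A missing selected feature at scoring time is a schema error, never
imputed.

## 4. Outcome evaluation

* **ROC/AUC** — Mann–Whitney probability with 0.5 for ties; CI by DeLong's
  structural-components method (the CI method behind reported AUC
  intervals is otherwise unspecified, DeLong is the field default).
* **KM / log-rank / Cox** — lifelines: product-limit with Greenwood bands,
  K-group log-rank, Cox partial likelihood with Efron tie handling (the
  standard default; note exact invariance under subject duplication holds
  for Breslow, Efron perturbs it slightly). Multivariate models enter
  covariates passing a univariate p < 0.05 screen; the full-covariate fit
  is also available.
* **C-index** — Harrell's concordant fraction over usable pairs (earlier
  time is an event), predictor ties 0.5; CI by seeded bootstrap (1000
  draws by default).
* **Nomogram** — per-covariate points scale the Cox linear-predictor
  contribution so the largest single-covariate span equals 100 points;
  reference is each covariate's low-hazard end. Only the linear
  predictor/points are computed, not a rendered chart.
* **Response tables** — objective response = CR+PR, disease control =
  CR+PR+SD, rates per RS group as percentages (empty group → NaN, never
  0); χ² on the group × category table; two-tailed unpaired t-tests of RS
  across OR/SD/PD. No multiple-testing correction is applied across
  subgroup analyses.

## 5. The synthetic cohort generator

The generator is the study bed for everything above; it is a pure function
of (config, seed).

* **Phantom** — 48³ voxels at 1 mm isotropic by default. A smooth
  abdominal-like background (40 ± 8 HU, 6 mm correlation) carries a
  randomly perturbed ellipsoidal tumor (radii 6–10 mm, smooth boundary
  bumps, largest connected component kept). Tumor interior and the 0–4 mm
  peritumoral shell are stationary Gaussian random fields: white noise
  smoothed with a Gaussian kernel whose width *is* the correlation length,
  renormalized to the target SD. An air pocket (−1000 HU, probability
  0.25) sits away from the tumor to exercise the exclusion rule. HU are
  clamped to [−1024, 3071].
* **Planted class effect** — NLR-High texture has 4 mm correlation length,
  NLR-Low 2 mm, both at SD 15 HU and equal mean (45 HU) in both regions,
  so the class signal is purely textural (GLCM/GLRLM/NGTDM statistics
  respond smoothly to correlation length; first-order features carry
  almost nothing). A Mix case takes the High-class parameters in the
  region whose NLR ≥ 1 and the Low-class parameters in the other — the
  direct image-side translation of the Mix-1/Mix-2 label semantics.
* **NLR values** — per region, a lymphocyte count (Poisson(60)+5) and a
  log-normal ratio conditioned on the region's high/low state, with the
  neutrophil count rounded so the ≥1 / <1 constraint holds exactly; Mix
  subtypes are chosen with equal probability.
* **Survival** — Weibull proportional hazards (shape 1.2, scale 90
  months), linear predictor = class log-HR (High log 2.5, Mix log 1.6,
  Low 0) + modest covariate effects (age, T, N, M). OS = DFS + an
  exponential residual (mean 8 months), so DFS ≤ OS by construction.
  Censoring: each case is censored with probability `censoring_rate`
  (default 0.3) and a censored case's observation time is uniform on
  (0, T) — this hits the requested censoring fraction exactly and keeps
  "rate 0 → all events", at the cost of censoring that is not independent
  of T; parameter-recovery tests (Cox HR within 3 SE at n = 2000) pass
  under this scheme. PFS uses the same structure on a 10-month scale.
* **Response** — a categorical CR/PR/SD/PD draw per class with
  Low-responds-most ordering; no tumor-volume dynamics or RECIST
  volumetry.
* **Truth side-channel** — `truth.json` records the class sequence, which
  texture parameters differ between classes (the planted informative
  directions), and the survival/response generator parameters, enabling
  recovery tests.

What the generator does **not** emulate: real anatomy and organ adjacency,
contrast-phase or scanner effects, segmentation variability, correlated
covariates, and NLR count distributions of any real cohort (no public
distributional data exists; the count model is a placeholder). Passing
tests therefore demonstrate that the pipeline's machinery is correct and
that it recovers planted structure — not clinical performance on real CT.

## 6. Problem sizes used by tests and benchmarks

The default benchmark cohort is 240 cases at 48³ (≈1 s per case to
generate, ring and extract); the out-of-fold AUC experiment refits the full
signature per outer fold. Unit tests use 32³–64³ phantoms, 2 000-subject
survival simulations for parameter recovery, and exhaustive oracles only on
≤21³ (geometry) or ≤5³ (texture) grids. These sizes were chosen so the
whole suite runs in a couple of minutes on one CPU while keeping every
statistical check adequately powered.

## 7. Known limitations

* The catalogue is a plausible reconstruction of a 584-feature pool, not a
  certified IBSI benchmark run; hooks to verify individual features against
  the IBSI digital phantom exist (the per-family functions take raw level
  grids) but no external data ships with the package.
* mRMR with F-statistic relevance is scale-mismatched against the
  correlation redundancy term (see §3).
* DeLong CIs are asymptotic; at AUC ≈ 1 they degenerate to a point.
* The nomogram point scale assumes monotone per-covariate effects over the
  stated covariate ranges.
* Resampling is voxel-grid zoom, not a full world-coordinate resampler; it
  assumes axis-aligned volumes (all NIfTI written by this package is).
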