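# Methods

## Scope and data model

The package operates on three-dimensional CT-like volumes (`VolumeGrid`:
Hounsfield intensities, positive anisotropic spacing in mm, origin) and
binary masks on the same grid (`MaskVolume`).  Coordinates are 0-based voxel
indices with `world = origin + index · spacing`; axis order is (x, y, z)
with z cranio-caudal.  Volumes and masks round-trip through NIfTI
(nibabel), with spacing and origin taken from the affine.

Network inference (vertebra detection, CNN segmentation) is deliberately out
of scope: the MIP module produces the inputs and training targets such
networks consume, and the evaluation/radiomics stages accept externally
supplied masks.

## Segmentation metrics

* `dsc` = 2|A∩B|/(|A|+|B|).
* `csa_error` = (B − A)/B × 100 on physical areas, positive when the
  automatic mask under-segments.  The per-case value uses total
  cross-sectional area summed over axial slices (equivalently volume /
  slice thickness), giving one number per vertebra; a per-slice variant is
  provided.
* `asd`: surface voxels are mask voxels with ≥ 1 face-adjacent background
  voxel; distances are exact Euclidean distance-transform values between
  surface voxel centres, spacing-aware.  The default is one-sided (A → B);
  `symmetric=True` averages both directions.  Both conventions are exposed
  because the distinction matters for asymmetric errors (thick rinds).
* Cohort summaries report median and [Q1, Q3] with linear-interpolation
  (type-7) quartiles.

## Training losses

`L = α L_bce + β L_dice + γ L_prop` with defaults α = β = γ = 1 (the
balancing weights are problem-specific and exposed).  BCE clips
probabilities to [1e−7, 1 − 1e−7]; Dice loss adds 1e−6 to numerator and
denominator so empty masks are defined; propagation loss is the fraction of
propagation-label pixels the prediction misses, defined 0 for an empty
propagation label.  The Dice/propagation contracts are written against
predicted *labels*; passing soft probabilities yields the soft variants used
for differentiable training.

## MIP preprocessing

Bone extraction chains Otsu thresholding, hysteresis-style region growing
(components of the supra-threshold set are kept when they contain a voxel in
the upper quarter of the supra-threshold range), closing with a 3³ cube, an
area opening removing components under 27 voxels, and global histogram
equalization (ECDF mapping to (0, 1]) of retained voxels.  The area opening
replaces a geometric opening deliberately: cortical shells are ~1.5 mm thin
and a 3³ opening erases them, while component-size filtering removes speckle
without touching large structures.  Equalization is global, not adaptive.

The propagation label for slice *i* is `erode(U) ∪ (U ∩ current)` where U is
the union of neighbour slices within ±window (current slice excluded) and
the erosion uses a 2-D cross.  A slice consistent with its neighbours maps
to itself; a slice with a destroyed band is filled from intact neighbours up
to a one-pixel rim.  This is one concrete instantiation of
neighbour-propagation, isolated behind a single function so alternatives can
be swapped.

## Radiomics

Extraction standardizes geometry first (trilinear resampling of intensities,
nearest-neighbour for masks; default target 0.29 × 0.29 × 0.70 mm, native
spacing available for small inputs), then discretizes masked intensities to
64 bins over mean ± 3 SD (mask-restricted moments; half-open bins, last bin
closed; out-of-range values clipped into the end bins; a zero-variance
region maps to the middle bin).

The catalog is a fixed 280-entry manifest:

| image source | families | count |
|---|---|---|
| original | morphology (21, mask-only), local intensity (2), statistics (20), histogram (23), GLCM (25), GLRLM (16), GLSZM (16), NGLDM (17), NGTDM (5) | 145 |
| LoG σ = 1, 2, 3 mm | local intensity (2), statistics (20), histogram (23) | 135 |

Conventions that pin feature values: 26-connected neighbourhoods and the 13
unique distance-1 directions; GLCM symmetrized per direction, normalized,
then averaged over directions; GLRLM merged over directions (run percentage
divides by voxels × directions); GLSZM zones are 26-connected constant-level
components; NGLDM coarseness α = 0 with dependence count j = 1 + equal-level
neighbours; NGTDM excludes voxels without in-mask neighbours.  Morphology
uses marching-cubes mesh volume/area, PCA axis lengths (4√λ), convex-hull
and bounding-box densities; intensity peaks average over a 1 cm³ sphere.
The statistics family includes the 25th/75th percentiles alongside the usual
IBSI set.  Ratio features whose reference collapses on degenerate masks
(single voxel, coplanar sets) return 0 rather than NaN, and the extractor
asserts every emitted value is finite.  The LoG filter demeans its input
before filtering so the truncated kernels return exactly zero on constants.

The twelve signature features map to catalog keys directly; the signature's
LoG features use the σ = 1 mm entries (the finest scale shipped).

## Selection cascade

1. Zero-variance removal compares values rounded to 12 significant digits of
   the column's largest magnitude, so storage round-off cannot hide a
   constant.
2. Standardization (mean 0, SD 1 with n−1 denominators) is learned on
   training data and frozen; test tables reuse the training parameters.
3. Stability: Lin's CCC with population (1/n) moments,
   `2 s_xy / (s_x² + s_y² + (x̄ − ȳ)²)`; a feature is kept when its *minimum*
   CCC over all repeat-segmentation tables strictly exceeds the threshold
   (default 0.90) — the conservative aggregation.  Degenerate rules: both
   vectors constant with equal means → 1, otherwise any constant vector → 0.
4. Correlation pruning visits pairs with |Pearson r| above threshold in
   descending |r| and drops the member with the larger univariable
   association p-value — two-sided Mann–Whitney U by default (rank-based and
   scale-free); a logistic Wald alternative is provided.
5. LASSO: logistic regression with L1 penalty (liblinear,
   `intercept_scaling = 1000` to keep the intercept effectively
   unpenalized), over 100 penalties log-spaced four decades below
   λ_max = max|Xᵀ(y − ȳ)|/n.  λ* follows the one-standard-error rule: the
   largest penalty whose mean stratified five-fold cross-validated binomial
   deviance lies within one standard error of the minimum.  The exact
   minimizer is fold-noise dominated when the signal is strong, which makes
   support recovery unstable; the 1-SE rule is the standard remedy and is
   the default (`one_se=False` restores the exact minimizer, ties toward the
   sparser model).  The final model is refit on all data at λ*, and the
   decision cutoff is chosen by the Youden index on the training scores.

## Diagnostic statistics

AUC is the Mann–Whitney concordance probability (half credit for ties),
identical to the trapezoidal area under the empirical ROC; its CI and the
paired model comparison use DeLong structural components.  A degenerate
zero-variance comparison reports z = 0, p = 1.  Proportions carry Wilson 95%
intervals.  The exact McNemar p is `min(1, 2·P[X ≤ min(b, c)])` with
X ~ Binomial(b + c, ½) and p = 1 when no discordant pairs exist.  Youden
cutoffs scan midpoints between adjacent distinct scores (plus sentinels
outside the range), returning the lowest maximizing cutoff; classification
calls malignant at score ≥ cutoff (ties malignant).

The shipped published signature stores its standardization parameters as
unspecified — they were never released — so applying it to new raw data is
explicitly not reproducible; `score` expects pre-standardized inputs for it.

## Synthetic phantoms

A phantom is a single vertebral body (no posterior elements): an elliptic
cylinder, default semi-axes 16 × 12 mm and height 26 mm on a 96 × 96 × 64
grid at 0.5 × 0.5 × 1 mm.  The cortical shell is the ≤ 1.5 mm rind of the
body's interior distance transform at 800 HU; the trabecular interior is
150 HU plus a smooth correlated texture field (SD 30 HU) and white noise
(SD 20 HU) over the whole volume.  Fracture classes: chronic benign —
anteriorly wedged height loss only; acute benign — the same compression plus
a sclerotic band (default +250 HU) under the superior endplate; malignant —
a lytic sphere (default radius 6 mm at −20 HU) centred on the anterior
cortex so it breaches the shell.  The HU constants give class-separable
features and are configurable.

Observer re-segmentations displace the boundary through a level-set offset
of the signed Euclidean distance function by a smooth Gaussian random field
(4 mm correlation length) scaled so ~1.5 SD reaches the displacement budget
and hard-clipped at ±displacement; since the distance function has unit
gradient the boundary never moves farther than the budget.  The largest
component is kept and holes filled, preserving single-body topology.  On
coarse grids, displacements below the voxel pitch may flip no voxels — the
discrete grid cannot represent them.

Cohorts jitter per-case anatomy and biology around the base parameters:
body size ±10%, compression U(0.10, 0.35), trabecular density N(0, 35) HU,
lesion radius ×U(0.5, 1.15), lesion density N(−20, 60) HU, and sclerosis
fraction U(0, 1) of the base band.  The wide lesion/sclerosis variation is a
realism choice: not every acute benign fracture is sclerotic and some lytic
lesions are small or near-isodense, so cohort discrimination is high but
imperfect rather than saturated — matching the regime radiomics studies of
this task actually report.  Patients own one to three vertebrae of one
class, exercising the one-vertebra-per-patient random selection.

What the phantoms do *not* emulate: CT physics (beam hardening,
reconstruction kernels), posterior elements and touching vertebrae,
paravertebral soft-tissue anatomy, and real fracture-morphology diversity.
Passing tests therefore demonstrate the correctness and robustness of the
measurement pipeline, not clinical performance on patient data.

## Experiment and test problem sizes

Cohort-scale runs (selection-cascade demonstrations, the parity experiment,
the acceptance script) use a reduced phantom — 72 × 72 × 56 grid, semi-axes
12 × 9 mm, height 20 mm, lesion radius 5 mm — with features extracted at
native spacing; these sizes keep whole suites in the minutes range while
preserving every qualitative property of the default phantom.  The parity
experiment uses 60 cases (30 per class), split in half by patient: the
signature is trained on one half's reference-mask features and evaluated on
the held-out half against features re-extracted from 0.5 mm- and
3 mm-perturbed masks, comparing paired AUCs with the DeLong test.  Held-out
evaluation is essential here: in-sample scores saturate and make
segmentation effects invisible.

## Reproducibility

Every stochastic component is a pure function of (parameters, seed).  A
single global seed fans out to per-stage, per-case streams through a
splitmix-style derivation (`vertomics.utils.derive_seed`), so stages are
independently reproducible; CLI artifacts embed a hash of their full
configuration.
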