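# Methods

`petrad` re-implements, end to end, a radiomic analysis of primary-tumour
FDG-PET uptake for predicting lymph-node (LN) metastases in endometrial
cancer: feature extraction inside the tumour volume of interest (VOI),
univariate screening, a small neural-network multivariate model, and a
unified rule that OR-combines the radiomic prediction with the clinician's
visual nodal reading. Because no patient imaging is available, a synthetic
cohort generator provides data with the statistical structure the analysis
assumes; this note records the model, the defaults, and the design choices
that were genuinely open.

## Imaging model and feature set

Volumes are body-weight SUV grids on 2.73 × 2.73 × 3.27 mm voxels; masks are
single 26-connected lesions with at least two voxels. All connectivity used
anywhere in the package (zones, dependence counts, neighbourhoods,
component labelling) is 26-connectivity.

The feature roster is frozen at 44 names:

* **SUV/volume (4)** — SUVmax, SUVmean, MTV (mL), TLG = SUVmean × MTV.
* **Shape (6)** — solidity (mask voxels over convex-hull voxels, hull
  membership decided on voxel centers in physical coordinates with an
  inclusive boundary test at 1e-9; rank-deficient point clouds fall back to
  the hull in the spanned affine subspace), sphericity
  π^⅓(6V)^⅔/A, compactness V/(√π·A^1.5), surface area (exposed voxel faces ×
  face areas), maximum 3D diameter between voxel centers, and elongation
  √(λ₂/λ₁) of the spatial covariance. Shape features use the anisotropic
  spacing; everything else is index-order agnostic.
* **First-order histogram (7)** — mean, population SD, skewness, excess
  kurtosis, coefficient of variation, base-2 entropy and uniformity over 64
  equal-width bins spanning the in-VOI range. A constant VOI takes the
  degenerate convention skew = kurtosis = CV = 0, entropy 0, uniformity 1.
* **Texture (27)** — computed on the VOI after equal-width quantization to
  N = 64 levels over the in-VOI [min, max]; the maximum clamps into level N
  and a constant VOI quantizes to level 1 everywhere. Families:
  co-occurrence (GLCM: entropy, energy, contrast, homogeneity,
  dissimilarity, correlation; NGLCM: the normalized matrix's entropy,
  energy, contrast, homogeneity, correlation), grey level size zone matrix
  (GLSZM: zone percentage ZP, small/large-zone emphases, grey-level and
  zone-size nonuniformities, low/high grey-level zone emphases),
  neighbourhood grey tone difference matrix (NGTDM: the five Amadasun–King
  features), and neighbourhood grey level dependence matrix (NGLDM:
  small/large-number emphases with dependence weighted as d + 1, number
  nonuniformity, entropy; coarseness parameter a = 0).

GLCM and NGLCM share one direction-aggregated symmetric accumulation over
the 13 unique 3D offsets (both orientations); the two name-spaces are a
documented redundancy. Neighbourhoods are restricted to the mask; no
padding value is invented. NGTDM coarseness for a constant VOI is capped at
10⁶; co-occurrence correlation of a constant VOI is defined as 1.

Zone percentage, the feature the analysis turns on, is the total number of
equal-level 26-connected zones divided by the VOI voxel count: a wide
uptake range makes each quantization bin wide, merges fluctuations into few
large zones, and lowers ZP; a narrow range fragments the VOI into many
small zones and raises it.

## Segmentation stand-in

The clinical contours in the original analysis came from a proprietary
iterative-thresholding tool whose algorithm is unpublished. The implemented
stand-in iterates T ← f · mean(SUV | mask) (optionally
background-corrected, T ← bg + f·(mean − bg)), keeping the 26-connected
component of {v ≥ T} containing the seed; defaults f = 0.42, initial mask
at 40 % of SUVmax. Voxels exactly at threshold are included. The initial
threshold never excludes the seed voxel itself, so any in-lesion seed is
usable. Convergence is detected as a repeated voxel set; an oscillation or
the iteration cap returns the last mask flagged `converged: False`. No
equivalence with the clinical contours is claimed, and every downstream
stage accepts externally supplied masks.

## Synthetic cohort generator

A tumour is a lobulated ellipsoid of uniform base uptake. Lobulation is a
low-order (l = 2, 3) spherical-harmonic radial perturbation whose amplitude
scales the fractional boundary excursion — a smooth, parameterized control
of concavity for solidity. Heterogeneous lesions add (i) a central necrotic
sub-ellipsoid covering a configurable volume fraction at a configurable
fraction of the base uptake, and (ii) focal hot spots — Gaussian uptake
bumps in the viable rim. The composed image is blurred with a Gaussian PSF
(default FWHM 5 mm, the emulated post-reconstruction filter), then white
Gaussian noise is added and the image clipped at zero. Background sits at
5 % of the base uptake. The mask is the pre-blur lobulated ellipsoid.

The default recovery-study conditions (used by `petrad.experiments` and
`scripts/acceptance.py`) generate cohorts of 86 patients, 16 LN-positive:

* LN-positive tumours: 10–70 mL (log-uniform), lobulation 0.3; with
  probability 0.8 the full heterogeneity signature — necrotic core
  (fraction 0.3, uptake ratio 0.1) plus 3 hot spots (peak 2.5–3.5 × base,
  radius 9 mm).
* LN-negative tumours: 3–35 mL, homogeneous, lobulation 0.05.
* Both classes: base SUV uniform 6–18, noise SD 5 % of base SUV, PSF 5 mm.
* Visual reading: Bernoulli labels at 50 % sensitivity / 99 % specificity;
  scanner ids round-robin.

Why this shape. The generator's purpose is to reproduce the documented
statistical structure: node-positive tumours are larger (higher MTV/TLG),
more heterogeneous in uptake, and more irregular in outline. Direct
simulation shows that a deep necrotic core *alone* does not lower ZP on
this voxel grid: the blurred core interface fragments into many one-voxel
zones and outweighs the bin-width widening, for every noise model and
lesion size tried. Wide uptake range achieved through *focal high* uptake,
by contrast, stretches the quantization range at almost no interface cost,
and together with the core reproduces the expected behaviour — lower ZP in
heterogeneous lesions at matched sizes — robustly. The hot-spot component
is therefore part of the default heterogeneity signature, and the size link
mirrors the documented MTV/TLG association.

What the generator does not emulate: sinogram-level reconstruction physics,
spatially correlated noise, attenuation/scatter, inter-scanner texture
bias beyond the PSF/noise settings, and diffuse multi-scale biological
texture. Consequences worth knowing: SUVmax carries some class signal here
(hot spots raise it) although it did not in the clinical cohorts, and the
low-variance pair statistics (co-occurrence contrast/dissimilarity, NGTDM
contrast) read the synthetic heterogeneity at least as strongly as ZP does,
so ZP is *a* top-ranking feature but rarely the single best — passing tests
show the pipeline recovers the planted structure, not that ZP would win the
feature ranking on real patients.

## Statistics

Univariate screening: two-sided Wilcoxon rank-sum per feature (exact
enumeration when the pooled sample is ≤ 20 without ties, tie-corrected
normal approximation with continuity correction otherwise — the default at
n = 86), rank AUC with ties counted ½ and orientation flipped so AUC ≥ 0.5,
and a Youden-optimal cut-off over midpoints of adjacent sorted unique
values (ties toward higher sensitivity, then the smaller threshold).
Classification at a cut-off is strict: a positive-low feature calls
positive iff value < cutoff. The screen applies the raw p ≤ 0.01 filter of
the published protocol; a Benjamini–Hochberg column is attached for
information only. Single-feature performance is assessed by leave-one-out:
direction and cut-off refitted on the other n − 1 patients for each
held-out patient.

Feature reduction is greedy: seed with the smallest-p (largest-AUC
tiebreak) feature, then admit features in increasing p order only while
p ≤ 0.01 and |Spearman ρ| < 0.85 against everything already kept.

## Neural-network model

One hidden layer of sigmoid units and a sigmoid output; inputs affinely
mapped to [−1, 1] using training-set min/max (a constant training input is
an error). Trainable parameters: (inputs + 1)·h + (h + 1) — 13 for two
inputs and three hidden neurons. The loss is cross-entropy with the
positive-case terms weighted ×4 (compensating the 16/70 imbalance;
implemented as a loss weight, not oversampling). Training is full-batch
Adam (lr 0.05), at most 500 epochs, early stopping on the validation loss
with patience 25 and restoration of the best weights; everything is
deterministic given the seed. The original work names no training
algorithm, epochs or stopping rule; these are this package's documented
choices.

Data splits follow the published rule: a pool of n patients is divided into
train/validation at the 72 : 13 ratio (val = round(n·13/85), remainder to
training), stratified so the validation positive count is
round(val_n × prevalence), clamped so both parts keep both classes.
Leave-one-out assessment runs `n_sessions` sessions (default 20); in each,
every held-out patient is predicted by a network trained on a fresh seeded
split of the remaining pool, and the session confusion yields
sensitivity/specificity/gmean (√(sens·spec)). Both the split and the
initialization are re-seeded per session. Stepwise backward model selection
starts from all candidate features, evaluates every single-feature removal
× hidden size ∈ {2, 3, 4, 5} by mean gmean, accepts the best removal only
on strict improvement, and breaks ties toward fewer inputs, then fewer
neurons, then lexicographic names. The final model is an ensemble (default
200 members, each trained on a fresh seeded split of the whole cohort)
whose output is the mean member output, classified at 0.5 — the decision
threshold is this package's choice, as the original never states one.

## Unified framework and reporting

The unified rule is a logical OR of visual detection and the radiomic
prediction: it can only gain sensitivity and only lose specificity relative
to either component (exact theorems, tested as such). A sequential variant
— radiomics applied only to visually negative patients — is algebraically
identical for binary outputs. Rates are reported as integer percent with
half-up rounding (69/70 → 99 %), applied only at reporting time. Scanner
robustness of a feature is checked a posteriori with a Kruskal–Wallis test
across scanner groups.

One documented inconsistency in the source material: the stated prevalences
(23 % / 45 %) disagree with the tabulated counts (16/86 = 18.6 %,
9/29 = 31 %). The package trusts the counts wherever they matter.

## Problem sizes used in tests and the acceptance script

Texture matrices are verified against independent brute-force
constructions on 1000 random VOIs in 4×4×4 grids at ≤ 4 levels. The
recovery study runs 20 independent 86-patient cohorts. Null calibrations
use 1000 rank-test draws and 500 Kruskal–Wallis draws; the label-permuted
model-selection check runs 10 permutations on 30-patient cohorts with
single-session leave-one-out, a deliberately small configuration that
preserves the selection-bias structure being measured.
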