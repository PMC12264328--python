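# Methods

This note documents the models, conventions and numerical choices behind
`radstab`, in the spirit of a package's methods appendix: what is
computed, under which assumptions, with which defaults, and what the
synthetic test-bed does and does not establish.

## Uncertainty model

A stochastic segmentation model yields `T ≥ 2` probability maps per scan
(`T = 50` by default, matching common Monte-Carlo-dropout practice; the
scaled-down runs use `T = 20`). From the replicate probabilities `p_it`:

* mean prediction `p̄_i = (1/T) Σ_t p_it`, binarized at 0.5 into the MP
  mask, with the tie `p̄ = 0.5` mapped to foreground (a deterministic
  convention);
* aleatoric uncertainty `(1/T) Σ_t p_it (1 − p_it)` — the mean Bernoulli
  variance of the replicates;
* epistemic uncertainty `(1/T) Σ_t (p_it − p̄_i)²` — the **population**
  (1/T, not 1/(T−1)) variance of the replicate probabilities;
* predictive uncertainty = their sum, which collapses algebraically to
  `p̄_i (1 − p̄_i)` and is therefore bounded by 0.25. The test-suite
  asserts the identity to 1e−12; any violation indicates a broken
  implementation, not numerical noise.

Confidence-level masks classify each replicate at 0.5 first (the
classification cutoff is configurable; a published cutoff for the voting
step is generally not stated in this literature) and then include a voxel
in `CL_th` iff at least `th`% of replicates vote foreground, inclusive.
Nesting `CL_100 ⊆ … ⊆ CL_10` holds by construction.

Both soft losses carry an additive smoothing constant `ε = 1e−6` in
numerator and denominator so the all-empty case is defined (loss 0),
standard soft-Dice practice. The hard Dice score returns 1 when both
masks are empty.

The KL separability metric histograms predictive uncertainty separately
for misclassified (MP ≠ ground truth) and correctly classified voxels on
shared bin edges spanning the pooled range, 20 bins, one count of
additive (Laplace) smoothing per bin, natural logarithm, and reports
KL(incorrect ‖ correct). Bin count, smoothing and log base are our
choices; none is canonical. When no voxel is misclassified the metric is
reported as *undefined* (an exception, or NaN in pipeline tables), never
as zero — zero means "uncertainty is uninformative", absence of errors
means "nothing to separate".

## Radiomics

Preprocessing follows thick-slice abdominal MRI practice: intensities are
clamped to `[μ − 0.5σ, μ + 4σ]` (population σ over the volume) and the
clamped volume min–max rescaled to `[0, 255]`; volumes are resampled to
1.458 × 1.458 × 5.5 mm (B-spline for images, nearest-neighbour for masks,
so masks stay binary and all mask sources land on the same grid);
intensities are then z-scored using whole-volume statistics
(ROI-restricted statistics are a configuration away; whole-volume is the
default because standardization precedes mask-dependent extraction).
Gray levels are discretized with a fixed bin count of 64 over the ROI
intensity range per slice.

The feature roster is pinned to exactly 105 names shipped in code
(`radstab.radfeat.FEATURE_NAMES`, also exportable as a JSON manifest):
18 first-order, 14 shape, 22 GLCM, 16 GLRLM, 16 GLSZM, 14 GLDM and
5 NGTDM features following the IBSI definitions. Relative to the common
24-feature GLCM roster, `SumAverage` (a deterministic multiple of
`JointAverage` under symmetry) and `MCC` are omitted to pin the total at
105.

Because through-plane resolution (5.5 mm) is far coarser than in-plane
resolution, first-order and texture features are computed on each 2-D
slice intersecting the mask and averaged, unweighted, over contributing
slices; a value a degenerate slice leaves undefined (e.g. no co-occurring
pairs in a single-voxel ROI) is NaN and excluded from the average rather
than silently zeroed. Shape descriptors are the exception: they are
computed once in 3-D (marching-cubes mesh volume and surface area,
PCA axis lengths of the physical voxel coordinates, boundary-voxel
maximum 2-D diameters), because a per-slice "volume" is not a volume —
the cubic scaling law for `shape_MeshVolume` and its use as the volume
surrogate in feature filtering both require the 3-D quantity.

Texture conventions worth stating: GLCM is symmetric, distance 1, four
2-D directions, feature values averaged over directions (matrix-level
quantities cross-checked against scikit-image's `graycomatrix`); GLRLM
uses the same four directions; GLSZM zones are 8-connected; GLDM uses
α = 0 and dependence size k = 1 + (number of 8-neighbours in the ROI with
equal level), the +1 keeping k ≥ 1; NGTDM neighbourhood averages exclude
the centre and non-ROI voxels, with the usual guard values (coarseness
1e6 when its denominator vanishes, contrast 0 for a single gray level).

## Reliability analysis

ICC forms are computed directly from the two-way crossed ANOVA mean
squares: consistency `ICC(3,k) = (MS_R − MS_E)/MS_R` and absolute
agreement `ICC(2,k) = (MS_R − MS_E)/(MS_R + (MS_C − MS_E)/n)`; both are
average-measure ("multiple raters") forms and may be negative. The tests
cross-check both against pingouin to 1e−10. A design with no
between-target variance has no defined ICC; it is reported as NaN and a
NaN counts as below-cutoff in the class taxonomy (conservative, and it
preserves the property that the four classes partition the feature set).

Design layouts: ICC_S treats the individual scans (subject × repeat) of
one group as targets and the two mask sources (ground truth vs method) as
raters, computed per group; ICC_A treats subjects as targets and the
repeat acquisitions as raters, with both groups pooled — scan–rescan
variability is assumed group-independent, and pooling doubles the number
of targets in a small cohort. Classes are counted per group; when the
two groups select different `th_opt`, each group's class counts use its
own threshold while the pooled ICC_A is evaluated at that same threshold.

`th_opt` minimizes the class-4 count; ties go to the larger class-1
count, residual ties to the smallest threshold (an arbitrary but
deterministic convention).

Wilcoxon comparisons of ICC distributions are two-tailed paired
signed-rank tests over features: exact null for n ≤ 25 without zero
differences, normal approximation with continuity correction otherwise,
Pratt handling when zero differences occur, and the all-zero case
reported as degenerate with p = 1. No multiplicity correction is applied
across comparisons.

## Classification

Candidate features are those repeatable w.r.t. scan–rescan variability
(classes 1∪3 at `th_opt`, intersected across groups). Filtering drops
zero-variance columns and columns with |Pearson r| > 0.8 against
`shape_MeshVolume` (retaining the volume itself). MRMR uses the FCQ
quotient criterion — ANOVA F-statistic relevance divided by the mean
|Pearson correlation| with the already-selected set. A difference
criterion was considered and rejected: the F statistic is unbounded while
correlations live in [0, 1], so subtraction effectively ignores
redundancy (an exact duplicate of the top feature survives it). The
redundancy denominator is floored at 0.01, and candidates nearly
collinear with a selected feature (max |r| > 0.95) are deferred until no
alternatives remain. Selection frequency is aggregated over 500
bootstrap resamples of the scans; the five most frequent features win,
ties broken by column order.

The classifier is an unpenalized logistic regression inside
leave-one-patient-out cross-validation (all repeat scans of one subject
held out together; per-fold z-standardization from training folds only).
On complete separation the unpenalized fit diverges and a light ridge
penalty (C = 100) is substituted. ROC and AUC are computed at scan level
over the pooled out-of-fold predictions. DeLong's test for correlated
ROC curves is implemented with the fast midrank placement-value
estimator; its AUC equals Mann–Whitney pair counting exactly, and its
type-I error is verified by simulation in the test-suite.

## Synthetic cohort

The generator produces what the analysis needs statistically, not
anatomically realistic MRI. Each subject has two ellipsoidal "kidneys"
with per-subject random semi-axes (±5%) and in-plane orientation; the CKD
group's volumes are shifted by −20% and its interior texture-noise
amplitude by +50% by default (recovered by direct measurement in the
tests). Interiors carry a low-frequency intensity gradient plus
band-limited Gaussian texture; the background is darker with independent
noise. Default grids are 12 × 64 × 64 voxels at 1.458 × 1.458 × 5.5 mm;
the acceptance runs use 10 × 48 × 48 to keep a full end-to-end run around
two minutes on one CPU.

Repeat acquisitions share the anatomy and differ by a rigid transform —
3-D translation (SD 3 mm per axis) plus a small in-plane rotation (SD
3°) — followed by linear resampling of the intensity volume and an
independent acquisition-noise draw (SD 6 intensity units). The
through-plane translation matters most: with 5.5 mm slices it changes
which planes cut the object, which is the dominant scan–rescan effect in
this geometry, and without it ground-truth-mask features were so
repeatable that the stability analysis saturated. Masks are evaluated
analytically from the transformed ellipsoids, so they are exactly binary
with no resampling artifacts.

Replicate probability maps are `sigmoid(−(d + bias + δ_t)/s)` where `d`
is the signed Euclidean distance to the ground-truth boundary (voxel EDT
with a half-pitch correction so boundary-layer voxels sit at sub-voxel
distances), `s = band_width/4`, and `δ_t` is a smooth Gaussian random
field (6 mm correlation length, RMS `replicate_jitter`). The smooth-field
family is a modelling choice; real network disagreement has unknown
spatial statistics. With `calibration < 1`, up to six Gaussian patches
per scan are blended in at locations away from the uncertain band, with
probabilities noisy around the *correct* label (≈0.7/0.3) — high
aleatoric uncertainty decoupled from actual error locations, which is
exactly what a miscalibrated model produces. Four named profiles
(`mcd-like`, `tta-like`, `mcd-plus-like`, `tta-plus-like`) encode
narrow/broad uncertainty bands crossed with poor/good calibration.

What the synthetic tests do show: the machinery is correct (identities,
oracles, nesting, selection rules), injected effects are recoverable, a
calibrated profile yields higher KL separability than a miscalibrated
one, and confidence-level masks at `th_opt` do not lose repeatable
features relative to the deterministic-analog MP masks. What they do not
show: magnitudes observed on real kidney MRI — real cohorts have
observer-dependent manual contours, physiological and protocol
variability, and network error structure none of which this phantom
reproduces, so feature counts and AUCs here should be read as
demonstrations of the pipeline's behaviour, not as clinical estimates.

## Known limitations

* Texture-matrix gray-level dimensions use the levels present in each
  slice ROI; engines that keep fixed 64-level matrices can differ in
  level-count-dependent features (e.g. Idmn/Idn normalizers).
* Maximum 2-D diameters use boundary voxel centres, not mesh vertices; on
  coarse grids this understates diameters by up to one voxel pitch.
* The pooled ICC_A design assumes scan–rescan variability is independent
  of group; the per-group ICC_S design cannot detect rater-by-target
  interactions with only two mask sources.
* `simulate_prob_stack` perturbs the signed distance along the boundary
  normal only; tangential disagreement patterns (e.g. consistent
  mis-segmentation of one pole) are not represented.
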