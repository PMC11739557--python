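# Methods

## The model

`ssmpca` implements the scaled subprofile model / principal component
analysis (SSM/PCA) family of multivariate methods for metabolic brain
imaging. The data model for a cohort of spatially normalized FDG-PET
scans is multiplicative: a subject's scan is a global scaling factor
times a shared metabolic topography modulated by a small number of
spatial covariance sources,

    scan_s(v) = g_s * exp( T(v) + sum_k a_{s,k} C_k(v) + eps_s(v) )

where `T` is the population mean log-intensity image, `C_k` are spatial
component maps, `a_{s,k}` subject loadings, `eps_s` residual noise, and
`g_s` an uninteresting per-subject global factor (dose, weight, scanner
gain). Taking logs turns `g_s` into an additive constant per subject, so
removing each subject's mean across voxels cancels it **exactly** — the
central identity the whole pipeline rests on. Removing the control-group
mean at each voxel afterwards ("double centering") expresses every
subject as a residual profile relative to the normal reference.

PCA of the residual matrix recovers the covariance sources. With far
more voxels than subjects the voxel-space covariance is rank-deficient;
we eigendecompose the small subjects × subjects Gram matrix `Y Yᵀ` and
map eigenvectors back to voxel space (`Y ᵀ u / √λ`), which yields the
identical non-null spectrum at a fraction of the cost. Components are
unit-norm and mutually orthogonal; the sign of each is fixed by the
convention that the patient group's mean score is at least the control
group's (PCA signs are otherwise arbitrary, and disease patterns are
conventionally reported as patient-elevated).

A *disease-related pattern* is a linear combination of components that
best separates patients from controls. We take the shortest prefix of
components whose cumulative variance fraction reaches the variance
target (default 50%), then search all subsets of those candidates up to
a maximum size (default 4), fitting a logistic regression of group on
component scores for each subset, and keep the subset with the smallest
AIC. The pattern is the coefficient-weighted sum of the winning
components, rescaled to unit norm; the rescaling factor is recorded, and
affects raw scores only by a constant factor that the z-transform
absorbs. Where maximum likelihood diverges (complete separation, common
in small well-separated cohorts) a ridge-penalized logistic fit with a
fixed small penalty (C = 10) supplies finite coefficients, and its AIC
is computed from the penalized fit's log-likelihood.

## Prospective scoring

A new scan's expression score is

    score = ( log-profile − row-mean − reference_offset ) · weights

with `reference_offset` the control-mean row-centered log profile saved
at derivation. The subtraction shifts all scores equally and is absorbed
by z-transformation, but keeping it makes prospective scores numerically
identical to the derivation subject scores rather than merely affinely
related. Scoring involves no other scan, so it is order-independent and
single-subject computable. Scores are z-transformed so the reference
controls have mean 0, SD 1 (n−1 denominator). A validation cohort
without its own controls is standardized against the derivation
controls' stored mean/SD — the standard practice when no independent
control sample exists, at the price of a possible derivation bias that
users should keep in mind.

## Bootstrap topography validation

Stability of the voxel weights is assessed by resampling subjects with
replacement *within* each group (preserving the two-group design the
logistic step needs; pooled resampling is available as an option),
re-running the entire derivation on each resample, sign-aligning each
resampled pattern to the point estimate (flip when the inner product is
negative), and forming per-voxel percentile confidence intervals from
the stack. Voxels whose interval contains zero are zeroed. Percentile
rather than BCa intervals: with ~1000 draws and no bias-correction
machinery the percentile method is transparent and adequate for a
sign-crossing decision. The PC-subset search is re-run per iteration but
capped at the point estimate's subset size; freezing the subset verbatim
is a switch (`freeze_subset`), since both behaviors are established.
Degenerate resamples (a group collapsing to a single distinct subject,
or a rank-zero residual matrix) are redrawn with a capped retry count.

## Pattern comparison

Topographic overlap of two patterns on a common grid is the Pearson
correlation of their voxel weights over the intersection of their masks,
restricted to voxels non-zero in *both* patterns (a union-with-zeros
variant is behind a flag). The associated p-value is reported but
flagged: voxel weights are spatially autocorrelated, and no
autocorrelation correction is applied, so the nominal p treats far too
many voxels as independent. Subject-level agreement is the Pearson
correlation of z-scores across a shared cohort.

## Summary-statistics inference

Clinical tables print group mean ± SD and n. The pooled one-way ANOVA F
is an exact function of these: between-groups SS from the group means
around the size-weighted grand mean, within-groups SS = Σ (n_g−1)·sd_g²,
df = (k−1, N−k); likewise the pooled two-sample t (and F = t² with
df (1, N−2) for ANOVA-style reporting). SDs in printed tables are
assumed to use the n−1 denominator, the universal convention. Pooled
(not Welch) variants are used so degrees of freedom match conventional
clinical reporting. Values reconstructed from summaries rounded to one
decimal carry input-rounding error of order 1–2% in F. Raw-data tests
(ANOVA, Kruskal–Wallis with tie correction, χ² without continuity
correction, paired t / Wilcoxon, Pearson/Spearman, Shapiro–Wilk and a
Lilliefors-style KS check) wrap scipy; Dunn's post-hoc z-statistics
(large-sample rank formula with tie correction) and Bonferroni
adjustment (p·m capped at 1) are computed directly, as no installed
package provides them.

## The synthetic cohort generator

The generator emulates exactly the structure the pipeline inverts, which
makes recovery tests sharp: a 32³ grid of 6 mm voxels (a realistic
downsampled PET field of view), an ellipsoidal phantom whose
high-intensity shell (intensity 100 against an interior of 25 and
background of 2, ±8% smooth radial ripple) plays the role of gray
matter — shell voxels exceed 35% of the image maximum, nothing else
does; K = 3 smooth orthonormal component maps built by smoothing white
noise on the shell and Gram–Schmidt orthogonalization; subject loadings
N(0, 1) with the patient mean of component 1 shifted by `effect_size`
loading-SDs (default 3); smooth log-space noise of SD 0.005 per voxel;
global scales uniform on [0.8, 1.25]. Loadings are O(1) on unit-norm
maps, so each component modulates a voxel's log intensity by ~1% and the
latent components dominate the between-subject covariance, with additive
noise an order of magnitude below — the regime in which a covariance
pattern is a meaningful object. Clinical covariates are linear in the
component-1 loading plus noise, tuned so the within-patient correlation
between tremor score and loading is ≈ −0.5, the magnitude typical of
clinical-imaging couplings.

Default group sizes are 18 controls + 16 patients (derivation) and 8
validation patients, so tests run at the scale of the cohort design the
package emulates.

What the generator does **not** emulate: PET physics (Poisson count
noise, resolution modeling, partial-volume effects, attenuation or
scatter), anatomy (no real gray-matter geometry), registration error,
or scanner harmonization. Passing recovery tests therefore demonstrates
the correctness of the covariance machinery under the model's own
assumptions, not performance on real scans.

## Numerical choices

- Masking: each derivation scan is thresholded at the fraction of its
  *own* maximum (default 0.35) and the masks intersected, guaranteeing
  strictly positive intensities in every retained voxel for every
  subject — a precondition of the log transform. Smoothing (if used)
  precedes masking.
- Smoothing uses σ = FWHM / (2√(2 ln 2)) per axis in voxel units with
  reflect boundary handling (preserves the local mean at the brain
  edge); an 8 mm FWHM kernel is the field's default.
- Voxel vectorization order: ascending C-order linear index, fixed per
  mask, making every vector deterministic.
- Centering is exact to machine precision and asserted at 1e-10; the
  Gram-route PCA agrees with dense SVD at 1e-8 after sign alignment;
  eigenvalues below 1e-12 of the largest are treated as null space.
- Degenerate inputs are rejected with messages naming the subject and
  voxel where possible (non-positive masked intensity, all-zero volume,
  empty mask intersection, zero reference variance, rank-zero residual).

## Problem sizes

The test suite exercises a 20³-grid cohort of 8+8(+4) subjects for unit
tests and the full 32³, 18+16(+8) design for end-to-end recovery (20
seeds) and the effect-size sweep; bootstrap checks use 30–50 iterations.
`scripts/acceptance.py` uses the full design with 20 seeds and a
50-iteration bootstrap. These sizes were chosen to probe the paper-scale
design while keeping a complete run in the low tens of seconds on one
CPU; all operating-point defaults in the API remain the conventional
ones (1000 bootstrap iterations at a 95% CI).

## Known limitations

- The logistic subset search is exhaustive up to the size cap; with many
  candidate PCs and a larger cap the cost grows combinatorially.
- AIC subset selection on small cohorts is variable across resamples;
  the bootstrap propagates, rather than hides, that variability.
- The voxel-weight correlation p-value ignores spatial autocorrelation
  (flagged in the result object).
- Patterns are compared on a common grid only; no resampling between
  grids is provided — inputs are assumed pre-aligned to a common space,
  and spatial normalization is explicitly out of scope.
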