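# ssmpca

Scaled subprofile model PCA (SSM/PCA) for metabolic spatial covariance
patterns in FDG-PET — derive a disease-related pattern from a mixed
patient/control cohort, validate its topography by bootstrap, score new
scans prospectively, compare pattern topographies, and reproduce
cohort-level statistics from raw data or printed summary tables.

Intended for neuroimaging researchers analyzing spatially normalized
PET (or PET-like) volumes, and for anyone who wants a transparent,
fully tested reference implementation of the SSM/PCA pipeline with a
built-in synthetic-cohort generator for validation.

## The method

For scans normalized to a common space, restricted to a gray-matter
mask (voxels ≥ 35% of each scan's maximum, intersected across
subjects), the pipeline computes subject residual profiles

    y_s = log x_s − mean_v(log x_s) − mean_{controls}(·)

(log transform; subject-mean removal, which cancels global scaling
exactly; control-mean removal). PCA of the residual matrix `Y` in voxel
space — computed via the subjects × subjects matrix `Y Yᵀ` — yields
orthonormal voxel components (group-invariant subprofiles) with subject
scores. Components covering the top 50% of variance enter a logistic
regression of group on scores; the AIC-best subset (up to 4 components)
is linearly combined with its fitted coefficients into a unit-norm
voxel-weight pattern. A new scan's expression score is the projection
of its centered log profile onto the pattern, z-transformed so the
control group has mean 0 and SD 1. Bootstrap resampling within groups
(conventionally 1000 iterations, 95% CI) retains only voxels whose
weight confidence interval excludes zero.

See `docs/methods.md` for assumptions, parameter choices and
limitations.

## A worked example

Each script in `examples/` demonstrates one capability. Simulating a
42-subject cohort (18 controls, 16 patients, 8 held-out validation
patients) with a disease shift of 3 loading-SDs on the first of three
embedded covariance components, deriving the pattern and scoring
everyone (`examples/02_derive_pattern.py`, `examples/03_prospective_scoring.py`)
prints:

```
analysis mask: 7608 voxels
first PCs explain 68.7%, 17.9%, 11.0% of residual variance
selected PCs (0-based): [0], logistic coefficients: [4.16]
recovered pattern vs ground-truth component 1: |r| = 0.976

derivation controls: mean z = -0.000 (0 by construction)
derivation patients: mean z = +4.025
validation patients: mean z = +4.323 (n = 8)
```

The derived voxel weights correlate at |r| = 0.976 with the component
the generator embedded — the pipeline recovered the planted disease
source — and held-out patients score as high as derivation patients,
i.e. the pattern generalizes. Bootstrap validation
(`examples/04_bootstrap_validation.py`) reports the fraction of voxels
whose weights keep their sign under cohort resampling, and
`examples/06_cohort_statistics.py` recomputes published group statistics
(ANOVA F, t, χ²) directly from printed mean ± SD / n table rows:

```
age:              F(2,39) = 2.226, p = 0.121
tremor severity:  F(2,33) = 39.064, p = 2e-09
disease duration: t(22) = -1.768 (F = 3.124), p = 0.091
gender balance:   chi2(2) = 0.00, p = 1.00
```

A thin CLI wraps the same calls for shell use:

```bash
ssmpca simulate --seed 0 --out cohort/
ssmpca derive --scans cohort/scans --labels cohort/covariates.csv \
    --derivation-groups control,patient --out pattern/
ssmpca score --scans cohort/scans --labels cohort/covariates.csv \
    --pattern pattern/ --out scores.csv
ssmpca bootstrap --scans cohort/scans --labels cohort/covariates.csv \
    --iterations 1000 --ci 0.95 --seed 0 --out boot/
```

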