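"""Scaled subprofile model PCA: derive a disease-related covariance pattern.

The derivation pipeline, applied to a combined patient/control sample of
spatially normalized scans restricted to a common gray-matter mask:

1. log-transform the masked intensities (``build_profiles``);
2. double-center: remove each subject's mean across voxels, then remove
   the control-group mean at each voxel (``double_center``) — subject
   centering cancels per-subject global scaling exactly, control
   centering expresses every profile relative to the normal reference;
3. PCA of the residual matrix in voxel space, computed through the
   subjects x subjects Gram matrix (``run_pca``);
4. keep the shortest prefix of components covering the target fraction
   of variance (``select_components``, default 50%);
5. logistic regression of group membership on component scores, with an
   exhaustive AIC-based subset search, and linear combination of the
   winning components weighted by their fitted coefficients
   (``fit_logistic_combination`` + ``build_pattern``).

The result is a unit-norm voxel-weight vector — the disease-related
spatial covariance pattern — packaged with everything needed to score
new scans prospectively.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .volumes import Volume, BinaryMask, vectorize, devectorize, write_volume, write_mask, read_mask

__all__ = [
    "SubjectProfileMatrix",
    "PCABasis",
    "CovariancePattern",
    "build_profiles",
    "double_center",
    "run_pca",
    "select_components",
    "fit_logistic_combination",
    "build_pattern",
    "derive_pattern",
    "save_pattern",
    "load_pattern",
]

_EIG_TOL = 1e-12


@dataclass
class SubjectProfileMatrix:
    """Subjects x masked-voxels matrix at a named preprocessing state."""

    values: np.ndarray
    state: str  # raw | log | subject_centered | residual
    subject_ids: list[str]
    group_labels: list[str]
    mask: BinaryMask
    control_label: str = "control"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("profile matrix must be 2-D (subjects x voxels)")
        if self.values.shape[0] != len(self.subject_ids) or len(self.subject_ids) != len(self.group_labels):
            raise ValueError("row count, subject_ids and group_labels must agree")
        if self.values.shape[1] != self.mask.n_voxels:
            raise ValueError("column count must equal mask.n_voxels")

    @property
    def control_rows(self) -> np.ndarray:
        return np.array([g == self.control_label for g in self.group_labels])


@dataclass
class PCABasis:
    """Orthonormal voxel components with subject scores and variance shares."""

    voxel_components: np.ndarray   # K x voxels, unit-norm orthogonal rows
    subject_scores: np.ndarray     # subjects x K
    variance_fractions: np.ndarray # K, non-increasing


@dataclass
class CovariancePattern:
    """A derived voxel-weight pattern plus its scoring provenance.

    ``weights`` is unit-norm; ``norm_factor`` records the norm of the raw
    coefficient combination so the linear relation to the logistic fit is
    preserved. ``reference_offset`` is the control-mean row-centered log
    profile subtracted during scoring; ``control_score_mean``/``sd`` are
    the raw-score statistics of the derivation controls used for the
    z-transform of prospective scans.
    """

    weights: np.ndarray
    mask: BinaryMask
    selected_pcs: list[int]
    coefficients: np.ndarray
    reference_offset: np.ndarray
    norm_factor: float = 1.0
    control_score_mean: float = 0.0
    control_score_sd: float = 1.0
    id: str = "pattern"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.size != self.mask.n_voxels:
            raise ValueError("weights length must equal mask.n_voxels")
        if not np.any(self.weights):
            raise ValueError("pattern weights are all zero")


def build_profiles(
    scans: Sequence[Volume],
    mask: BinaryMask,
    labels: Sequence[str],
    control_label: str = "control",
) -> SubjectProfileMatrix:
    """Log-transform the masked intensities of each scan (state=log)."""
    if len(scans) != len(labels):
        raise ValueError("one label per scan required")
    rows = np.empty((len(scans), mask.n_voxels))
    for i, v in enumerate(scans):
        profile = vectorize(v, mask)
        if np.any(profile <= 0):
            j = int(np.argmax(profile <= 0))
            raise ValueError(
                f"non-positive masked voxel in subject {v.id!r} (mask voxel {j}); "
                "the log transform requires strictly positive intensities"
            )
        rows[i] = np.log(profile)
    return SubjectProfileMatrix(
        rows, "log", [v.id for v in scans], list(labels), mask, control_label
    )


def double_center(p: SubjectProfileMatrix) -> tuple[SubjectProfileMatrix, np.ndarray]:
    """Row-center each subject, then remove the control-group voxel mean.

    Returns the residual matrix (state=residual) together with the
    control-mean vector (the ``reference_offset`` kept for prospective
    scoring). Row centering makes every profile invariant to global
    multiplicative scaling of the scan; control centering expresses each
    residual relative to the normal group.
    """
    if p.state != "log":
        raise ValueError(f"expected state 'log', got {p.state!r}")
    ctrl = p.control_rows
    if not ctrl.any():
        raise ValueError("no control subjects to center against")
    centered = p.values - p.values.mean(axis=1, keepdims=True)
    reference_offset = centered[ctrl].mean(axis=0)
    residual = centered - reference_offset
    out = SubjectProfileMatrix(
        residual, "residual", p.subject_ids, p.group_labels, p.mask, p.control_label
    )
    return out, reference_offset


def run_pca(p: SubjectProfileMatrix) -> PCABasis:
    """PCA of the residual matrix in voxel space via the subject-space Gram matrix.

    With far more voxels than subjects the voxel-space covariance is rank
    deficient; its nonzero spectrum equals that of the small
    subjects x subjects matrix ``Y Y^T``, whose eigenvectors map back to
    voxel space as ``Y^T u / ||.||``. Components come out unit-norm and
    orthogonal; ``variance_fractions`` are eigenvalues over the trace.
    """
    if p.state != "residual":
        raise ValueError(f"expected state 'residual', got {p.state!r}")
    y = p.values
    if y.shape[0] < 3:
        raise ValueError("PCA requires at least 3 subjects")
    gram = y @ y.T
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    total = evals.sum()
    if total <= _EIG_TOL:
        raise ValueError("residual matrix has rank 0 (all residuals zero)")
    keep = evals > _EIG_TOL * evals[0]
    evals, evecs = evals[keep], evecs[:, keep]
    comps = (y.T @ evecs).T          # K x voxels
    comps /= np.sqrt(evals)[:, None]  # unit norm: ||Y^T u|| = sqrt(lambda)
    scores = y @ comps.T
    basis = PCABasis(comps, scores, evals / total)
    _orient_components(basis, p)
    return basis


def _orient_components(b: PCABasis, p: SubjectProfileMatrix) -> None:
    """Fix the PCA sign ambiguity: patient mean score >= control mean score."""
    ctrl = p.control_rows
    pat = ~ctrl
    if not pat.any():
        return
    delta = b.subject_scores[pat].mean(axis=0) - b.subject_scores[ctrl].mean(axis=0)
    flip = delta < 0
    b.voxel_components[flip] *= -1.0
    b.subject_scores[:, flip] *= -1.0


def select_components(b: PCABasis, variance_target: float = 0.5) -> list[int]:
    """Shortest prefix of PCs whose cumulative variance reaches the target.

    Indices are 0-based positions into the basis.
    """
    if not 0.0 < variance_target < 1.0:
        raise ValueError("variance_target must be in (0, 1)")
    cum = np.cumsum(b.variance_fractions)
    n = int(np.searchsorted(cum, variance_target) + 1)
    n = min(n, len(cum))
    return list(range(n))


def _logit_fit(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """Fit logistic regression; return (slopes, aic, penalized_flag).

    Maximum likelihood first; on failure to converge or (quasi-)complete
    separation, a ridge-penalized refit with a fixed small penalty.
    """
    import warnings

    import statsmodels.api as sm

    design = sm.add_constant(x, has_constant="add")
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
        params = np.asarray(res.params)
        converged = bool(res.mle_retvals.get("converged", False))
        if converged and np.all(np.abs(params) < 1e3):
            return params[1:], float(res.aic), False
    except Exception:
        pass
    # Ridge fallback (fixed small penalty keeps coefficients finite under
    # complete separation); AIC computed from the penalized fit's deviance.
    from sklearn.linear_model import LogisticRegression

    clf = LogisticRegression(C=10.0, solver="lbfgs", max_iter=2000)
    clf.fit(x, y)
    if not np.all(np.isfinite(clf.coef_)):
        raise RuntimeError("logistic regression failed to converge")
    eta = clf.decision_function(x)
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    k = x.shape[1] + 1
    return clf.coef_.ravel().copy(), 2.0 * k - 2.0 * ll, True


def fit_logistic_combination(
    b: PCABasis,
    candidate_pcs: Sequence[int],
    labels: Sequence[str],
    control_label: str = "control",
    max_subset_size: int = 4,
) -> tuple[list[int], np.ndarray]:
    """AIC-best logistic combination of component scores.

    Enumerates all non-empty subsets of ``candidate_pcs`` up to
    ``max_subset_size``, fits group ~ scores for each, and returns the
    subset minimizing AIC with its slope coefficients (intercept
    excluded: it carries no spatial information).
    """
    candidate_pcs = list(candidate_pcs)
    if not candidate_pcs:
        raise ValueError("candidate_pcs must be non-empty")
    y = np.array([0.0 if g == control_label else 1.0 for g in labels])
    if len(set(y)) < 2:
        raise ValueError("both groups must be present")
    best: tuple[float, list[int], np.ndarray] | None = None
    for size in range(1, min(max_subset_size, len(candidate_pcs)) + 1):
        for subset in itertools.combinations(candidate_pcs, size):
            x = b.subject_scores[:, list(subset)]
            coefs, aic, _ = _logit_fit(x, y)
            if best is None or aic < best[0] - 1e-12:
                best = (aic, list(subset), coefs)
    assert best is not None
    return best[1], np.asarray(best[2])


def build_pattern(
    b: PCABasis,
    selected_pcs: Sequence[int],
    coefficients: np.ndarray,
    reference_offset: np.ndarray,
    mask: BinaryMask,
    profiles: SubjectProfileMatrix | None = None,
    id: str = "pattern",
) -> CovariancePattern:
    """Combine selected components into a unit-norm voxel-weight pattern.

    ``weights = sum_i coef_i * component_i``, rescaled to unit norm; the
    rescaling factor is recorded (raw scores change by that factor only,
    which the z-transform absorbs). If the derivation profiles are given,
    the control raw-score mean/SD are stored for prospective z-scoring.
    """
    coefficients = np.asarray(coefficients, dtype=np.float64)
    selected_pcs = list(selected_pcs)
    if len(selected_pcs) != coefficients.size:
        raise ValueError("coefficients must align with selected_pcs")
    raw = coefficients @ b.voxel_components[selected_pcs]
    norm = float(np.linalg.norm(raw))
    if norm <= 0:
        raise ValueError("combined pattern vector is zero")
    pattern = CovariancePattern(
        weights=raw / norm,
        mask=mask,
        selected_pcs=selected_pcs,
        coefficients=coefficients,
        reference_offset=np.asarray(reference_offset, dtype=np.float64),
        norm_factor=norm,
        id=id,
    )
    if profiles is not None:
        ctrl = profiles.control_rows
        if profiles.state == "residual":
            raw_scores = profiles.values[ctrl] @ pattern.weights
        else:
            raise ValueError("profiles must be in state 'residual'")
        pattern.control_score_mean = float(raw_scores.mean())
        pattern.control_score_sd = float(raw_scores.std(ddof=1))
    return pattern


def derive_pattern(
    scans: Sequence[Volume],
    labels: Sequence[str],
    mask: BinaryMask,
    control_label: str = "control",
    variance_target: float = 0.5,
    max_subset_size: int = 4,
    id: str = "pattern",
) -> tuple[CovariancePattern, PCABasis]:
    """Full derivation: profiles -> double centering -> PCA -> selection -> combination."""
    profiles = build_profiles(scans, mask, labels, control_label)
    residual, offset = double_center(profiles)
    basis = run_pca(residual)
    candidates = select_components(basis, variance_target)
    selected, coefs = fit_logistic_combination(
        basis, candidates, labels, control_label, max_subset_size
    )
    pattern = build_pattern(basis, selected, coefs, offset, mask, residual, id=id)
    return pattern, basis


def save_pattern(p: CovariancePattern, out_dir: str | Path) -> None:
    """Persist a pattern: weight NIfTI + mask + reference offset + JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(devectorize(p.weights, p.mask, id=p.id), out / "weights.nii.gz")
    write_mask(p.mask, out / "mask.nii.gz")
    write_volume(
        devectorize(p.reference_offset, p.mask, id="reference_offset"),
        out / "reference_offset.nii.gz",
    )
    sidecar = {
        "id": p.id,
        "selected_pcs": [int(i) for i in p.selected_pcs],
        "coefficients": [float(c) for c in p.coefficients],
        "norm_factor": p.norm_factor,
        "control_score_mean": p.control_score_mean,
        "control_score_sd": p.control_score_sd,
    }
    (out / "pattern.json").write_text(json.dumps(sidecar, indent=2))


def load_pattern(in_dir: str | Path) -> CovariancePattern:
    src = Path(in_dir)
    meta = json.loads((src / "pattern.json").read_text())
    mask = read_mask(src / "mask.nii.gz")
    weights = vectorize_signed(src / "weights.nii.gz", mask)
    offset = vectorize_signed(src / "reference_offset.nii.gz", mask)
    return CovariancePattern(
        weights=weights,
        mask=mask,
        selected_pcs=meta["selected_pcs"],
        coefficients=np.asarray(meta["coefficients"]),
        reference_offset=offset,
        norm_factor=meta["norm_factor"],
        control_score_mean=meta["control_score_mean"],
        control_score_sd=meta["control_score_sd"],
        id=meta["id"],
    )


def vectorize_signed(path: str | Path, mask: BinaryMask) -> np.ndarray:
    """Read a possibly signed NIfTI map and extract the masked vector."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    return data.ravel(order="C")[mask.voxel_order].copy()
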