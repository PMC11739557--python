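"""Bootstrap validation of pattern topography.

Subjects are resampled with replacement within each group (group sizes
preserved), the full derivation is rerun on each resample, each
resampled pattern is sign-aligned to the point estimate, and per-voxel
percentile confidence intervals are formed from the stack of resampled
weights. Voxels whose interval contains zero are removed from the
pattern: what survives is the topography stable under sampling
variability of the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .volumes import Volume, BinaryMask
from .derive import (
    CovariancePattern,
    build_profiles,
    double_center,
    run_pca,
    select_components,
    fit_logistic_combination,
    build_pattern,
    derive_pattern,
)

__all__ = ["BootstrapResult", "bootstrap_pattern"]


@dataclass
class BootstrapResult:
    n_iterations: int
    ci_level: float
    voxel_lower: np.ndarray
    voxel_upper: np.ndarray
    thresholded_weights: np.ndarray
    n_surviving: int
    seed: int
    point_estimate: CovariancePattern
    iteration_weights: np.ndarray | None = None


def _stratified_resample(
    rng: np.random.Generator, labels: Sequence[str]
) -> np.ndarray:
    """Indices of a with-replacement resample drawn within each group."""
    labels = np.asarray(labels)
    idx = np.empty(labels.size, dtype=int)
    pos = 0
    for g in dict.fromkeys(labels.tolist()):  # preserve group block order
        members = np.flatnonzero(labels == g)
        draw = rng.choice(members, size=members.size, replace=True)
        idx[pos : pos + members.size] = draw
        pos += members.size
    return idx


def _pooled_resample(rng: np.random.Generator, labels: Sequence[str]) -> np.ndarray:
    n = len(labels)
    return rng.choice(n, size=n, replace=True)


def bootstrap_pattern(
    scans: Sequence[Volume],
    labels: Sequence[str],
    mask: BinaryMask,
    n_iterations: int = 1000,
    ci_level: float = 0.95,
    seed: int = 0,
    control_label: str = "control",
    variance_target: float = 0.5,
    max_subset_size: int = 4,
    stratified: bool = True,
    freeze_subset: bool = False,
    resampler: Callable[[np.random.Generator, Sequence[str]], np.ndarray] | None = None,
    max_retries: int = 20,
    keep_iteration_weights: bool = False,
) -> BootstrapResult:
    """Within-group bootstrap of the full pattern derivation.

    Parameters
    ----------
    n_iterations, ci_level:
        Operating point of the resampling scheme (conventionally 1000
        iterations at a 95% interval).
    stratified:
        Resample within groups (default) or pooled across the cohort.
    freeze_subset:
        If True, each iteration reuses the point estimate's selected PC
        subset verbatim instead of re-running the search; by default the
        search is rerun but capped at the point-estimate subset size.
    resampler:
        Override for the index-drawing function (used for degenerate
        no-variability checks).
    """
    if n_iterations < 2:
        raise ValueError("n_iterations must be >= 2")
    if not 0.0 < ci_level < 1.0:
        raise ValueError("ci_level must be in (0, 1)")

    point, _ = derive_pattern(
        scans, labels, mask, control_label, variance_target, max_subset_size
    )
    subset_cap = len(point.selected_pcs)

    if resampler is None:
        resampler = _stratified_resample if stratified else _pooled_resample
    rng = np.random.default_rng(seed)
    labels_arr = list(labels)
    scans = list(scans)

    # Profiles are resample-independent per subject; compute once and
    # index rows, rather than re-reading volumes every iteration.
    base = build_profiles(scans, mask, labels_arr, control_label)

    stack = np.empty((n_iterations, mask.n_voxels))
    for it in range(n_iterations):
        for attempt in range(max_retries + 1):
            idx = resampler(rng, labels_arr)
            sub_labels = [labels_arr[i] for i in idx]
            # Degenerate draw: a group collapsing to one distinct subject
            # leaves the logistic step and PCA ill-posed — redraw.
            degenerate = any(
                len({i for i, g in zip(idx, sub_labels) if g == grp}) < 2
                for grp in set(sub_labels)
            )
            if degenerate:
                if attempt == max_retries:
                    raise RuntimeError("bootstrap retry cap exceeded on degenerate resamples")
                continue
            try:
                from .derive import SubjectProfileMatrix

                prof = SubjectProfileMatrix(
                    base.values[idx],
                    "log",
                    [base.subject_ids[i] for i in idx],
                    sub_labels,
                    mask,
                    control_label,
                )
                residual, offset = double_center(prof)
                basis = run_pca(residual)
                if freeze_subset:
                    selected = [i for i in point.selected_pcs if i < basis.variance_fractions.size]
                    if not selected:
                        raise ValueError("frozen subset empty on resample")
                    x = basis.subject_scores[:, selected]
                    from .derive import _logit_fit

                    y = np.array([0.0 if g == control_label else 1.0 for g in sub_labels])
                    coefs, _, _ = _logit_fit(x, y)
                else:
                    candidates = select_components(basis, variance_target)
                    selected, coefs = fit_logistic_combination(
                        basis, candidates, sub_labels, control_label, subset_cap
                    )
                pat = build_pattern(basis, selected, coefs, offset, mask, residual)
            except (ValueError, RuntimeError):
                if attempt == max_retries:
                    raise RuntimeError("bootstrap retry cap exceeded on degenerate resamples")
                continue
            w = pat.weights
            if w @ point.weights < 0:  # sign-align to the point estimate
                w = -w
            stack[it] = w
            break

    alpha = (1.0 - ci_level) / 2.0
    lower = np.quantile(stack, alpha, axis=0)
    upper = np.quantile(stack, 1.0 - alpha, axis=0)
    surviving = (lower > 0) | (upper < 0)
    thresholded = np.where(surviving, point.weights, 0.0)
    return BootstrapResult(
        n_iterations=n_iterations,
        ci_level=ci_level,
        voxel_lower=lower,
        voxel_upper=upper,
        thresholded_weights=thresholded,
        n_surviving=int(surviving.sum()),
        seed=seed,
        point_estimate=point,
        iteration_weights=stack if keep_iteration_weights else None,
    )
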