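"""Synthetic normalized-PET cohorts with a known embedded covariance pattern.

The generative model is exactly the model the derivation pipeline inverts:

    scan_s = g_s * exp( T + sum_k a_{s,k} C_k + eps_s )

with ``T`` a fixed log-intensity brain template, ``C_k`` smooth orthonormal
spatial components supported on the gray-matter-like shell, ``a_{s,k}``
per-subject loadings whose component-1 mean is shifted in patients,
``eps_s`` smooth voxel noise in log space, and ``g_s`` a per-subject
multiplicative global scale. Because ``g_s`` is an additive constant in
log space, the log transform plus subject-mean centering removes it
exactly; recovery tests therefore probe the covariance machinery, not
nuisance handling.

Clinical covariates (a tremor severity score and a cognitive score) are
linear in the component-1 loading plus noise, emulating the coupling of
symptom scales to disease-pattern expression.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import Volume, BinaryMask, write_volume, write_mask

__all__ = ["SimulationConfig", "GroundTruth", "make_template", "simulate_cohort", "write_cohort"]

CONTROL = "control"
PATIENT = "patient"
VALIDATION = "validation"


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the study design this package targets: 18 controls and
    16 patients for derivation plus 8 held-out patients for prospective
    validation, three latent spatial components, and a disease shift of
    the component-1 loading expressed in loading-SD units.

    Units: spatial components are unit-norm over the ~7.6k shell voxels
    of the default grid, so a loading of 1 modulates each voxel's log
    intensity by roughly 1% — the latent components dominate the
    between-subject covariance, with smooth per-voxel noise (``noise_sd``,
    log units per voxel) an order of magnitude below them, as in a
    normalized PET cohort where anatomy-scale covariance outweighs
    residual scanner noise.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: float = 6.0
    n_controls: int = 18
    n_patients: int = 16
    n_validation: int = 8
    n_components: int = 3
    effect_size: float = 3.0
    loading_sd: float = 1.0
    noise_sd: float = 0.005
    global_scale_range: tuple[float, float] = (0.8, 1.25)
    covariate_slope: float = -1.0
    covariate_noise_sd: float = 1.732
    seed: int = 0

    def validate(self) -> None:
        if min(self.grid_shape) < 16:
            raise ValueError("grid too small to contain the brain ellipsoid (< 16 per axis)")
        if self.n_controls < 2 or self.n_patients < 2:
            raise ValueError("need at least 2 subjects per derivation group")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.loading_sd < 0 or self.noise_sd < 0:
            raise ValueError("loading_sd and noise_sd must be >= 0")
        lo, hi = self.global_scale_range
        if not 0 < lo <= hi:
            raise ValueError("global_scale_range must be a positive interval")


@dataclass
class GroundTruth:
    """Everything the generator knows and the pipeline tries to recover."""

    template_log: Volume
    shell_mask: BinaryMask
    components: np.ndarray          # K x n_shell_voxels, orthonormal rows
    loadings: np.ndarray            # subjects x K
    global_scales: np.ndarray       # subjects
    group_labels: list[str]
    covariates: pd.DataFrame        # subject_id, group, tremor_score, cognitive_score


def _ellipsoid_distance(shape: tuple[int, int, int]) -> np.ndarray:
    """Normalized ellipsoidal radius: 1.0 on the brain surface."""
    grids = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
    out = np.zeros(shape, dtype=np.float64)
    for g, n in zip(grids, shape):
        c = (n - 1) / 2.0
        semi = 0.42 * n  # brain fills ~84% of the field of view per axis
        out += ((g - c) / semi) ** 2
    return np.sqrt(out)


def make_template(cfg: SimulationConfig) -> tuple[Volume, BinaryMask]:
    """Build the baseline log-intensity brain and its gray-matter shell.

    The phantom is an ellipsoid with a high-intensity shell (the
    gray-matter analogue: intensity 100, above 35% of the maximum), a
    dimmer interior (white-matter analogue, below threshold) and faint
    background, plus smooth deterministic interior variation so the
    template is not piecewise constant.
    """
    cfg.validate()
    r = _ellipsoid_distance(cfg.grid_shape)
    shell = (r >= 0.62) & (r <= 1.0)
    interior = r < 0.62
    intensity = np.full(cfg.grid_shape, 2.0)
    intensity[interior] = 25.0
    intensity[shell] = 100.0
    # Smooth radial ripple, +-8% in the shell: keeps shell >= 35% of max.
    intensity *= 1.0 + 0.08 * np.cos(3.0 * np.pi * r)
    affine = np.diag([cfg.voxel_size_mm] * 3 + [1.0])
    template = Volume(np.log(intensity), affine, id="template_log")
    return template, BinaryMask(shell, affine)


def _smooth_field(rng: np.random.Generator, shape, support: np.ndarray, sigma_vox: float = 2.0) -> np.ndarray:
    """White noise smoothed on the grid, restricted to ``support`` voxels."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma_vox, mode="reflect")
    return f.ravel(order="C")[support]


def _orthonormal_components(rng: np.random.Generator, shape, support: np.ndarray, k: int) -> np.ndarray:
    """K smooth, mutually orthonormal voxel maps on the shell support.

    Built by smoothing white noise then Gram-Schmidt orthogonalization.
    """
    comps = np.empty((k, support.size))
    for i in range(k):
        v = _smooth_field(rng, shape, support)
        for j in range(i):
            v -= (v @ comps[j]) * comps[j]
        nrm = np.linalg.norm(v)
        if nrm < 1e-12:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("degenerate component draw")
        comps[i] = v / nrm
    return comps


def simulate_cohort(cfg: SimulationConfig) -> tuple[list[Volume], GroundTruth]:
    """Generate a full synthetic cohort and its ground truth.

    Returns scans ordered controls, patients, validation patients. The
    same seed always yields a bit-identical cohort.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    template, shell = make_template(cfg)
    support = shell.voxel_order
    comps = _orthonormal_components(rng, cfg.grid_shape, support, cfg.n_components)

    groups = (
        [CONTROL] * cfg.n_controls
        + [PATIENT] * cfg.n_patients
        + [VALIDATION] * cfg.n_validation
    )
    n = len(groups)
    loadings = rng.normal(0.0, cfg.loading_sd, size=(n, cfg.n_components))
    is_pat = np.array([g != CONTROL for g in groups])
    loadings[is_pat, 0] += cfg.effect_size * cfg.loading_sd
    lo, hi = cfg.global_scale_range
    gscales = rng.uniform(lo, hi, size=n)

    scans: list[Volume] = []
    flat_template = template.data.ravel(order="C")
    for s in range(n):
        log_img = flat_template.copy()
        log_img[support] += loadings[s] @ comps
        if cfg.noise_sd > 0:
            eps = _smooth_field(rng, cfg.grid_shape, support)
            sd = eps.std()
            if sd > 0:
                log_img[support] += cfg.noise_sd * eps / sd
        data = gscales[s] * np.exp(log_img.reshape(cfg.grid_shape))
        scans.append(Volume(data, template.affine, id=f"sub-{s:03d}"))

    # Tremor severity couples negatively to disease-component loading
    # (higher pattern expression, lower score), cognition positively.
    if cfg.loading_sd > 0:
        z_load = (loadings[:, 0] - loadings[:, 0].mean()) / cfg.loading_sd
    else:
        z_load = np.zeros(n)
    tremor = 30.0 + 10.0 * (
        cfg.covariate_slope * z_load + rng.normal(0, cfg.covariate_noise_sd, n)
    )
    cognitive = 25.0 + 3.0 * (
        -cfg.covariate_slope * z_load + rng.normal(0, cfg.covariate_noise_sd, n)
    )
    covariates = pd.DataFrame(
        {
            "subject_id": [v.id for v in scans],
            "group": groups,
            "tremor_score": tremor,
            "cognitive_score": cognitive,
        }
    )
    gt = GroundTruth(
        template_log=template,
        shell_mask=shell,
        components=comps,
        loadings=loadings,
        global_scales=gscales,
        group_labels=groups,
        covariates=covariates,
    )
    return scans, gt


def write_cohort(scans: list[Volume], gt: GroundTruth, cfg: SimulationConfig, out_dir: str | Path) -> None:
    """Persist a simulated cohort: NIfTI scans and components, CSV covariates, JSON config."""
    import json

    out = Path(out_dir)
    (out / "scans").mkdir(parents=True, exist_ok=True)
    for v in scans:
        write_volume(v, out / "scans" / f"{v.id}.nii.gz")
    write_volume(gt.template_log, out / "template_log.nii.gz")
    write_mask(gt.shell_mask, out / "shell_mask.nii.gz")
    from .volumes import devectorize

    for k in range(gt.components.shape[0]):
        write_volume(
            devectorize(gt.components[k], gt.shell_mask, id=f"component-{k + 1}"),
            out / f"component-{k + 1}.nii.gz",
        )
    gt.covariates.to_csv(out / "covariates.csv", index=False)
    cfg_dict = asdict(cfg)
    cfg_dict["grid_shape"] = list(cfg.grid_shape)
    cfg_dict["global_scale_range"] = list(cfg.global_scale_range)
    (out / "config.json").write_text(json.dumps(cfg_dict, indent=2))
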