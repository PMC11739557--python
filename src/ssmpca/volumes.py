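"""Volume handling: NIfTI I/O, smoothing, masking, and voxel vectorization.

All downstream stages operate on flat voxel vectors extracted from 3-D
grids through a :class:`BinaryMask`. The mask fixes a single voxel
ordering (ascending C-order linear index) so that every vector produced
from it is comparable element-by-element.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume",
    "BinaryMask",
    "read_volume",
    "write_volume",
    "gaussian_smooth",
    "threshold_mask",
    "combine_masks",
    "cohort_mask",
    "vectorize",
    "devectorize",
    "read_mask",
    "write_mask",
]

_AFFINE_ATOL = 1e-4


@dataclass
class Volume:
    """A single subject's 3-D intensity grid with voxel geometry.

    Parameters
    ----------
    data:
        Non-negative, finite 3-D intensity array.
    affine:
        4x4 grid-to-world transform (NIfTI convention).
    id:
        Subject or scan identifier.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3-D volume, got {self.data.ndim}-D")
        if any(s < 1 for s in self.data.shape):
            raise ValueError("all grid dimensions must be >= 1")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"volume {self.id!r} contains non-finite voxels")
        if np.any(self.data < 0):
            raise ValueError(f"volume {self.id!r} contains negative voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        """Physical voxel edge lengths in mm, from the affine."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def aligned_with(self, other: "Volume | BinaryMask") -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=_AFFINE_ATOL
        )

    def scaled(self, factor: float, id: str | None = None) -> "Volume":
        return Volume(self.data * factor, self.affine, id or self.id)


@dataclass
class BinaryMask:
    """The common analysis mask; defines the voxel vectorization order."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3-D")
        if not self.data.any():
            raise ValueError("mask has no true voxels")
        # Fixed bijection onto the true voxels: ascending C-order index.
        self._flat_index = np.flatnonzero(self.data.ravel(order="C"))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self._flat_index.size)

    @property
    def voxel_order(self) -> np.ndarray:
        """Linear C-order indices of the true voxels, ascending."""
        return self._flat_index

    def aligned_with(self, other: "Volume | BinaryMask") -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=_AFFINE_ATOL
        )


def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI-1 file as a :class:`Volume`.

    Rejects non-3-D images and images with NaN or negative voxels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3-D volume, got {data.ndim}-D in {path.name}")
    return Volume(data, np.asarray(img.affine), id=path.stem.removesuffix(".nii"))


def write_volume(v: Volume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(v.data, v.affine), str(path))


def read_mask(path: str | Path) -> BinaryMask:
    img = nib.load(str(path))
    return BinaryMask(np.asanyarray(img.dataobj) > 0.5, np.asarray(img.affine))


def write_mask(m: BinaryMask, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(m.data.astype(np.uint8), m.affine), str(path))


def gaussian_smooth(v: Volume, fwhm_mm: float) -> Volume:
    """Isotropic Gaussian smoothing with the kernel given in FWHM (mm).

    sigma per axis is ``fwhm / (2 sqrt(2 ln 2)) / voxel_size``; edges use
    reflection so the local mean near the brain boundary is preserved.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / v.voxel_size
    out = ndimage.gaussian_filter(v.data, sigma=sigma_vox, mode="reflect")
    # Smoothing of a non-negative image can produce tiny negative ringing
    # only through numerics; clip at 0 to preserve the Volume invariant.
    return Volume(np.clip(out, 0.0, None), v.affine, v.id)


def threshold_mask(v: Volume, fraction: float) -> BinaryMask:
    """Keep voxels at or above ``fraction`` of the whole-volume maximum.

    At the conventional 0.35 this retains mainly the gray-matter-like
    high-intensity compartment of a normalized PET image.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    vmax = float(v.data.max())
    if vmax <= 0:
        raise ValueError("all-zero volume has no maximum to threshold against")
    return BinaryMask(v.data >= fraction * vmax, v.affine)


def combine_masks(masks: Sequence[BinaryMask]) -> BinaryMask:
    """Intersection of aligned masks (voxel true iff true in all)."""
    if len(masks) == 0:
        raise ValueError("need at least one mask")
    first = masks[0]
    out = first.data.copy()
    for m in masks[1:]:
        if not first.aligned_with(m):
            raise ValueError("masks are not aligned")
        out &= m.data
    if not out.any():
        raise ValueError("empty intersection")
    return BinaryMask(out, first.affine)


def cohort_mask(scans: Sequence[Volume], fraction: float = 0.35) -> BinaryMask:
    """Common analysis mask for a derivation cohort.

    Each scan is thresholded at ``fraction`` of its own maximum and the
    per-scan masks are intersected, so every retained voxel carries
    above-threshold signal in every subject — a prerequisite for the log
    transform downstream.
    """
    return combine_masks([threshold_mask(v, fraction) for v in scans])


def vectorize(v: Volume, m: BinaryMask) -> np.ndarray:
    """Extract the masked voxels of ``v`` as a flat vector in mask order."""
    if not m.aligned_with(v):
        raise ValueError("volume and mask are not aligned")
    return v.data.ravel(order="C")[m.voxel_order].copy()


def devectorize(w: np.ndarray, m: BinaryMask, id: str = "") -> Volume:
    """Place a voxel vector back onto the mask's grid (zero elsewhere).

    Inverse of :func:`vectorize` on the mask support. Negative weights are
    legitimate here, so the result bypasses the Volume non-negativity check
    and is returned as a plain Volume whose data may be signed.
    """
    w = np.asarray(w, dtype=np.float64)
    if w.ndim != 1 or w.size != m.n_voxels:
        raise ValueError(
            f"vector length {w.size} does not match mask n_voxels {m.n_voxels}"
        )
    flat = np.zeros(int(np.prod(m.shape)), dtype=np.float64)
    flat[m.voxel_order] = w
    out = Volume.__new__(Volume)
    out.data = flat.reshape(m.shape)
    out.affine = m.affine.copy()
    out.id = id
    return out
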