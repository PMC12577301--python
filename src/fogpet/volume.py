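"""Volumetric image container, NIfTI-1 I/O, and intensity preprocessing.

The two preprocessing steps mirror the standard semi-quantitative FDG-PET
pipeline: each image is divided by its within-mask (global) mean so that
subjects are comparable without an arterial input function, and is then
smoothed with an isotropic-in-mm Gaussian kernel to improve signal-to-noise
before voxel-wise statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume",
    "VolumeFormatError",
    "NormalizationError",
    "read_volume",
    "write_volume",
    "normalize_global_mean",
    "gaussian_smooth",
    "fwhm_to_sigma",
]

#: FWHM of a Gaussian = 2*sqrt(2*ln 2) * sigma
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


class VolumeFormatError(ValueError):
    """Raised when a file is not a valid 3D NIfTI-1 volume."""


class NormalizationError(ValueError):
    """Raised when global-mean normalization is undefined (zero/non-finite mean)."""


@dataclass
class Volume:
    """A 3D scalar image with a voxel-to-world affine and optional binary mask.

    Parameters
    ----------
    data : (I, J, K) ndarray
        Scalar intensities; voxel indices are 0-based.
    affine : (4, 4) ndarray
        Voxel-to-world transform in mm. Must be invertible.
    mask : (I, J, K) bool ndarray, optional
        Binary analysis mask of the same shape as ``data``.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise VolumeFormatError(f"expected 3D volume, got {self.data.ndim}D")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise VolumeFormatError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise VolumeFormatError("affine is singular")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise VolumeFormatError(
                    f"mask shape {self.mask.shape} != data shape {self.data.shape}"
                )

    @property
    def voxel_size(self) -> np.ndarray:
        """Per-axis voxel edge lengths in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, ijk) -> np.ndarray:
        """Map 0-based voxel coordinates to world mm via the affine."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        hom = np.c_[ijk, np.ones(len(ijk))]
        out = (self.affine @ hom.T).T[:, :3]
        return out[0] if out.shape[0] == 1 else out


def read_volume(path, mask: np.ndarray | None = None) -> Volume:
    """Load a 3D NIfTI-1 file.

    Raises :class:`VolumeFormatError` (naming the file) if the file is
    malformed or not three-dimensional.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise VolumeFormatError(f"{path}: not a readable NIfTI file ({exc})") from exc
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim == 4 and data.shape[-1] == 1 else data
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected 3D volume, got {data.ndim}D")
    return Volume(data=np.asarray(data, dtype=np.float32), affine=img.affine, mask=mask)


def write_volume(vol: Volume, path) -> Path:
    """Write a volume as NIfTI-1 (.nii or .nii.gz), float32 data."""
    path = Path(path)
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    nib.save(img, str(path))
    return path


def normalize_global_mean(vol: Volume, target: float = 1.0) -> Volume:
    """Scale so the within-mask mean equals ``target``; zero outside the mask.

    Dividing by the global (within-mask) mean removes per-subject uptake
    scale — e.g. injected dose and body habitus — which is exactly the
    multiplicative nuisance the generator's subject factor emulates.
    """
    if vol.mask is None:
        raise NormalizationError("normalize_global_mean requires a mask")
    m = float(vol.data[vol.mask].mean()) if vol.mask.any() else np.nan
    if not np.isfinite(m) or m == 0.0:
        raise NormalizationError(f"in-mask mean is {m}; cannot normalize")
    out = np.where(vol.mask, vol.data * (target / m), 0.0).astype(np.float32)
    return replace(vol, data=out)


def fwhm_to_sigma(fwhm_mm: float, voxel_size_mm) -> np.ndarray:
    """Per-axis Gaussian sigma in voxel units for an isotropic-in-mm FWHM."""
    return np.asarray(fwhm_mm, dtype=float) / (np.asarray(voxel_size_mm, dtype=float) * FWHM_TO_SIGMA)


def gaussian_smooth(vol: Volume, fwhm_mm: float) -> Volume:
    """Separable Gaussian smoothing with FWHM given in mm (isotropic in mm).

    Voxel sizes are taken from the affine, so anisotropic grids get
    per-axis sigmas. The grid is zero-padded at its boundary; if the volume
    carries a mask it is re-applied afterwards. ``fwhm_mm == 0`` is the
    identity.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm_mm must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return replace(vol, data=vol.data.copy())
    sigma = fwhm_to_sigma(fwhm_mm, vol.voxel_size)
    out = ndimage.gaussian_filter(vol.data.astype(np.float64), sigma=sigma, mode="constant", cval=0.0)
    if vol.mask is not None:
        out = np.where(vol.mask, out, 0.0)
    return replace(vol, data=out.astype(np.float32))
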