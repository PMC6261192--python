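"""Image containers and NIfTI I/O.

An :class:`ImageVolume` is a 3-D scalar grid with geometry (per-axis voxel
spacing and origin, both in millimetres).  Axis convention throughout the
package: axis 0 = x (first in-plane index, medial-lateral), axis 1 = y
(second in-plane index, antero-posterior), axis 2 = z (slice axis).

A :class:`RoiMask` is a boolean grid aligned voxel-for-voxel with a volume;
it delineates the region (typically a gross tumor volume) on which radiomic
features are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

#: geometry comparisons tolerate this much disagreement (mm)
GEOMETRY_TOL_MM = 1e-4


@dataclass(frozen=True)
class ImageVolume:
    """3-D scalar image with voxel geometry.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Scalar intensities. ADC maps are in mm^2/s; DWI signals are in
        arbitrary units.
    spacing_mm : tuple of float
        Per-axis voxel size in mm; all entries positive.
    origin_mm : tuple of float
        World coordinate of voxel (0, 0, 0) in mm.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=float)
        if vox.ndim != 3:
            raise ValueError(f"volume must be 3-D, got shape {vox.shape}")
        if not np.all(np.isfinite(vox)):
            raise ValueError("volume contains non-finite voxels")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing_mm}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def same_grid(self, other: "ImageVolume | RoiMask", tol_mm: float = GEOMETRY_TOL_MM) -> bool:
        return (
            self.shape == other.shape
            and all(abs(a - b) <= tol_mm for a, b in zip(self.spacing_mm, other.spacing_mm))
            and all(abs(a - b) <= tol_mm for a, b in zip(self.origin_mm, other.origin_mm))
        )


@dataclass(frozen=True)
class RoiMask:
    """Binary region-of-interest mask aligned to an :class:`ImageVolume`."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError(f"mask must be 3-D, got shape {vox.shape}")
        vox = vox.astype(bool)
        if not vox.any():
            raise ValueError("mask is empty (no in-mask voxels)")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def same_grid(self, other: "ImageVolume | RoiMask", tol_mm: float = GEOMETRY_TOL_MM) -> bool:
        return ImageVolume.same_grid(self, other, tol_mm)  # type: ignore[arg-type]

    def values_in(self, volume: ImageVolume) -> np.ndarray:
        """Extract the in-mask intensities of an aligned volume (1-D array)."""
        if not self.same_grid(volume):
            raise ValueError(
                "mask and volume grids differ: "
                f"mask shape={self.shape} spacing={self.spacing_mm} origin={self.origin_mm}; "
                f"volume shape={volume.shape} spacing={volume.spacing_mm} origin={volume.origin_mm}"
            )
        return volume.voxels[self.voxels]


def _affine(spacing_mm, origin_mm) -> np.ndarray:
    aff = np.diag(list(spacing_mm) + [1.0])
    aff[:3, 3] = origin_mm
    return aff


def write_nifti(obj: ImageVolume | RoiMask, path) -> None:
    """Write a volume or mask as NIfTI-1 (.nii / .nii.gz)."""
    data = obj.voxels.astype(np.uint8) if isinstance(obj, RoiMask) else obj.voxels
    img = nib.Nifti1Image(data, _affine(obj.spacing_mm, obj.origin_mm))
    img.header.set_zooms(obj.spacing_mm)
    nib.save(img, str(path))


def _load(path):
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return img, spacing, origin


def read_volume(path) -> ImageVolume:
    """Read a 3-D NIfTI-1 scalar volume."""
    img, spacing, origin = _load(path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    return ImageVolume(data, spacing, origin)


def read_mask(path, threshold: float = 0.5) -> RoiMask:
    """Read a binary ROI mask from NIfTI-1; voxels > *threshold* are in-mask."""
    img, spacing, origin = _load(path)
    data = np.asarray(img.dataobj, dtype=float)
    return RoiMask(data > threshold, spacing, origin)
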