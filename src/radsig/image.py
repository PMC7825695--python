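"""In-memory containers for 3D scalar volumes and binary region masks.

Arrays are indexed ``(x, y, z)`` with a physical voxel spacing in mm per
axis.  Volumes and their masks live on the same lattice; every operation in
the package checks that alignment before touching voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume", "ROIMask", "read_volume", "read_mask"]


@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar image on a regular grid with physical spacing.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Scalar intensities; must be finite.
    spacing : tuple of float
        Voxel size in mm along each axis; strictly positive.
    origin : tuple of float
        Physical position (mm) of the center of voxel ``(0, 0, 0)``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels, dtype=np.float64)
        if v.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("volume contains non-finite intensities")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        object.__setattr__(self, "voxels", v)
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def with_voxels(self, voxels: np.ndarray) -> "ImageVolume":
        """Same geometry, new intensities."""
        return ImageVolume(voxels, self.spacing, self.origin)

    def to_nifti(self, path: str | Path) -> Path:
        """Write as NIfTI with a diagonal affine built from the spacing."""
        affine = np.diag(list(self.spacing) + [1.0])
        affine[:3, 3] = self.origin
        img = nib.Nifti1Image(self.voxels.astype(np.float32), affine)
        path = Path(path)
        nib.save(img, str(path))
        return path


@dataclass(frozen=True)
class ROIMask:
    """A binary region-of-interest mask aligned with an :class:`ImageVolume`."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    name: str = field(default="roi", compare=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {v.shape}")
        uniq = np.unique(v)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask voxels must be 0 or 1")
        v = v.astype(bool)
        if not v.any():
            raise ValueError("mask has no foreground voxels")
        sp = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in sp):
            raise ValueError("mask spacing must be positive")
        object.__setattr__(self, "voxels", v)
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def check_aligned(self, volume: ImageVolume) -> None:
        if self.shape != volume.shape or self.spacing != volume.spacing:
            raise ValueError(
                f"mask (shape {self.shape}, spacing {self.spacing}) is not on the "
                f"lattice of the volume (shape {volume.shape}, spacing {volume.spacing})"
            )

    def to_nifti(self, path: str | Path) -> Path:
        affine = np.diag(list(self.spacing) + [1.0])
        affine[:3, 3] = self.origin
        img = nib.Nifti1Image(self.voxels.astype(np.uint8), affine)
        path = Path(path)
        nib.save(img, str(path))
        return path


def _load(path: str | Path) -> tuple[np.ndarray, tuple, tuple]:
    path = Path(path)
    if path.suffix.lower() == ".nrrd":
        # NRRD goes through SimpleITK (optional dependency)
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img).T  # sitk is (z, y, x)
        return data, tuple(img.GetSpacing()), tuple(img.GetOrigin())
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(o) for o in img.affine[:3, 3])
    return data, spacing, origin


def read_volume(path: str | Path) -> ImageVolume:
    """Read a NIfTI (or NRRD) scalar volume; spacing from the header."""
    data, spacing, origin = _load(path)
    return ImageVolume(data.astype(np.float64), spacing, origin)


def read_mask(path: str | Path, name: str = "roi") -> ROIMask:
    """Read a NIfTI (or NRRD) binary mask (any nonzero voxel is foreground)."""
    data, spacing, origin = _load(path)
    return ROIMask((data > 0).astype(np.uint8), spacing, origin, name=name)
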