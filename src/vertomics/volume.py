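"""Volumetric containers, NIfTI I/O, resampling and intensity discretization.

Coordinate convention: 0-based voxel indices, world = origin + index * spacing,
axis order (x, y, z) with z the cranio-caudal axis.  Intensities are Hounsfield
units throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class VolumeGrid:
    """A 3-D scalar intensity volume on an anisotropic voxel grid.

    Parameters
    ----------
    intensities : (nx, ny, nz) float array of Hounsfield units.
    spacing_mm : voxel spacing along (x, y, z), all positive.
    origin_mm : world coordinate of voxel (0, 0, 0).
    """

    intensities: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 3:
            raise ValueError("intensities must be a 3-D array")
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensities must be finite")
        spacing = tuple(float(s) for s in self.spacing_mm)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError("spacing_mm must be 3 positive floats")
        object.__setattr__(self, "intensities", arr)
        object.__setattr__(self, "spacing_mm", spacing)
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass(frozen=True)
class MaskVolume:
    """A binary label volume sharing a :class:`VolumeGrid`'s grid geometry."""

    labels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be 0 or 1")
        spacing = tuple(float(s) for s in self.spacing_mm)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError("spacing_mm must be 3 positive floats")
        object.__setattr__(self, "labels", arr.astype(bool))
        object.__setattr__(self, "spacing_mm", spacing)
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def count(self) -> int:
        return int(self.labels.sum())

    def same_grid(self, other) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )


# ---------------------------------------------------------------------------
# NIfTI I/O


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def write_volume(volume: VolumeGrid, path) -> None:
    img = nib.Nifti1Image(
        volume.intensities.astype(np.float32), _affine(volume.spacing_mm, volume.origin_mm)
    )
    nib.save(img, str(path))


def write_mask(mask: MaskVolume, path) -> None:
    img = nib.Nifti1Image(
        mask.labels.astype(np.uint8), _affine(mask.spacing_mm, mask.origin_mm)
    )
    nib.save(img, str(path))


def read_volume(path) -> VolumeGrid:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(t) for t in img.affine[:3, 3])
    return VolumeGrid(np.asarray(img.dataobj, dtype=float), spacing, origin)


def read_mask(path) -> MaskVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(t) for t in img.affine[:3, 3])
    return MaskVolume(np.asarray(img.dataobj) > 0.5, spacing, origin)


# ---------------------------------------------------------------------------
# Resampling and discretization


def resample_to_spacing(volume, target_spacing_mm, is_mask: bool = False):
    """Resample a volume (or mask) onto an axis-aligned grid with new spacing.

    Physical extent is preserved to within one voxel per axis; intensities are
    interpolated trilinearly, masks by nearest neighbour.  The origin is kept.
    """
    target = tuple(float(s) for s in target_spacing_mm)
    if len(target) != 3 or any(s <= 0 for s in target):
        raise ValueError("target spacing must be 3 positive floats")
    arr = volume.labels.astype(float) if is_mask else volume.intensities
    old = volume.spacing_mm
    if np.allclose(old, target):
        out = arr.copy()
    else:
        new_shape = tuple(
            max(1, int(round(n * old[a] / target[a]))) for a, n in enumerate(arr.shape)
        )
        grids = np.meshgrid(
            *[np.arange(n) * target[a] / old[a] for a, n in enumerate(new_shape)],
            indexing="ij",
        )
        coords = np.stack([g.ravel() for g in grids])
        order = 0 if is_mask else 1
        out = ndimage.map_coordinates(
            arr, coords, order=order, mode="nearest"
        ).reshape(new_shape)
    if is_mask:
        return MaskVolume(out > 0.5, target, volume.origin_mm)
    return VolumeGrid(out, target, volume.origin_mm)


def quantize_intensities(volume: VolumeGrid, mask: MaskVolume, n_bins: int = 64, k_sd: float = 3.0):
    """Discretize masked intensities to 1..n_bins over the range mean ± k·SD.

    Values outside the range are clipped into the first/last bin.  The mean
    and SD are computed over masked voxels only.  A zero-SD (constant) region
    maps every voxel to the middle bin.

    Returns
    -------
    levels : int array, shape of the volume; 0 outside the mask, 1..n_bins inside.
    edges : (n_bins + 1,) bin edges in HU.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if mask.count() == 0:
        raise ValueError("empty mask")
    values = volume.intensities[mask.labels]
    mu = float(values.mean())
    sd = float(values.std())
    levels = np.zeros(volume.shape, dtype=np.int32)
    if sd == 0.0:
        edges = np.linspace(mu - 0.5, mu + 0.5, n_bins + 1)
        levels[mask.labels] = (n_bins + 1) // 2
        return levels, edges
    lo, hi = mu - k_sd * sd, mu + k_sd * sd
    edges = np.linspace(lo, hi, n_bins + 1)
    width = (hi - lo) / n_bins
    binned = np.floor((values - lo) / width).astype(np.int64) + 1
    levels[mask.labels] = np.clip(binned, 1, n_bins)
    return levels, edges
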