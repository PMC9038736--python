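"""Deterministic preprocessing for vertebra detection and segmentation:
bone extraction, maximum-intensity projections (full and thin-slab), fixed-size
cropping, cutout augmentation, two-plane VOI assembly, and propagation labels.

Plane conventions, with volume axes (x, y, z) and z cranio-caudal:
``coronal`` projects along y (pixels indexed by x, z); ``sagittal`` projects
along x (pixels indexed by y, z).  These images are what a 2-D detector or
segmenter would consume; no network inference happens here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .volume import VolumeGrid

PLANES = ("coronal", "sagittal")
_PROJECTION_AXIS = {"coronal": 1, "sagittal": 0}


@dataclass(frozen=True)
class MipImage:
    pixels: np.ndarray
    plane: str
    source_extent: tuple[int, int]  # half-open slab range along the projection axis
    offset: tuple[int, int] = (0, 0)  # crop/pad offset for coordinate back-mapping

    def __post_init__(self) -> None:
        if self.plane not in PLANES:
            raise ValueError(f"plane must be one of {PLANES}")
        object.__setattr__(self, "pixels", np.asarray(self.pixels, dtype=float))


@dataclass(frozen=True)
class Roi2D:
    """Half-open 0-based pixel bounds (u0, u1) x (v0, v1) of a 2-D detection."""

    u0: int
    u1: int
    v0: int
    v1: int

    def __post_init__(self) -> None:
        if not (self.u0 < self.u1 and self.v0 < self.v1):
            raise ValueError("ROI must have min < max per axis")


@dataclass(frozen=True)
class Voi3D:
    """Half-open voxel bounds of a 3-D volume of interest."""

    x0: int
    x1: int
    y0: int
    y1: int
    z0: int
    z1: int

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1 and self.z0 < self.z1):
            raise ValueError("VOI must have min < max per axis")


def preprocess_for_mip(volume: VolumeGrid) -> VolumeGrid:
    """Bone-enhancing chain: Otsu threshold, region growing, morphological
    filtering, histogram equalization.

    Region growing is hysteresis-style: connected components of the
    above-Otsu set are kept only if they contain a strong seed (upper quartile
    of the supra-threshold range).  Morphology is closing (3x3x3 cube) then an
    area opening dropping components under 27 voxels.  Equalization is
    global over retained voxels, mapped to [0, 1]; background is set to 0.
    """
    arr = volume.intensities
    if np.ptp(arr) == 0:
        raise ValueError("degenerate histogram: constant volume")
    t = float(threshold_otsu(arr))
    low = arr > t
    seed_level = t + 0.25 * (arr.max() - t)
    lab, n = ndimage.label(low)
    if n:
        has_seed = ndimage.maximum(arr, lab, index=np.arange(1, n + 1)) >= seed_level
        keep = np.zeros(n + 1, dtype=bool)
        keep[1:] = has_seed
        grown = keep[lab]
    else:
        grown = low
    # closing with a 3^3 cube fills cortical gaps; an area opening (dropping
    # components under 27 voxels) removes speckle without eroding thin shells
    # or chamfering large structures the way a geometric opening would
    filt = ndimage.binary_closing(grown, np.ones((3, 3, 3), dtype=bool))
    lab2, n2 = ndimage.label(filt)
    if n2:
        sizes = np.bincount(lab2.ravel())
        sizes[0] = 0
        filt = (sizes >= 27)[lab2]
    if not filt.any():
        filt = grown  # opening can erase very thin structures; fall back
    out = np.zeros_like(arr)
    vals = arr[filt]
    if vals.size:
        # global histogram equalization of retained intensities via the ECDF
        order = np.argsort(vals, kind="stable")
        ranks = np.empty(vals.size)
        ranks[order] = np.arange(1, vals.size + 1)
        out[filt] = ranks / vals.size
    return VolumeGrid(out, volume.spacing_mm, volume.origin_mm)


def project_mip(volume: VolumeGrid, plane: str, slab: tuple[int, int] | None = None) -> MipImage:
    """Maximum-intensity projection, optionally restricted to a thin slab
    (half-open index range along the projection axis)."""
    if plane not in PLANES:
        raise ValueError(f"plane must be one of {PLANES}")
    axis = _PROJECTION_AXIS[plane]
    n = volume.shape[axis]
    if slab is None:
        slab = (0, n)
    a, b = int(slab[0]), int(slab[1])
    if not (0 <= a < b <= n):
        raise ValueError("empty or out-of-bounds slab")
    sl = [slice(None)] * 3
    sl[axis] = slice(a, b)
    pixels = volume.intensities[tuple(sl)].max(axis=axis)
    return MipImage(pixels, plane, (a, b))


def crop_pad_to(image: MipImage, size: tuple[int, int] = (416, 416),
                center: tuple[int, int] | None = None) -> MipImage:
    """Crop and/or pad to a fixed pixel size with the content centred.

    Padding uses the image minimum.  The applied offset (position of input
    pixel (0,0) in the output, possibly negative) is recorded for coordinate
    back-mapping.
    """
    src = image.pixels
    out_h, out_w = int(size[0]), int(size[1])
    if center is None:
        cy, cx = src.shape[0] / 2.0, src.shape[1] / 2.0
    else:
        cy, cx = float(center[0]), float(center[1])
    # offset of input origin in output coordinates
    off_y = int(round(out_h / 2.0 - cy))
    off_x = int(round(out_w / 2.0 - cx))
    out = np.full((out_h, out_w), src.min(), dtype=float)
    ys0, ys1 = max(0, -off_y), min(src.shape[0], out_h - off_y)
    xs0, xs1 = max(0, -off_x), min(src.shape[1], out_w - off_x)
    if ys0 < ys1 and xs0 < xs1:
        out[ys0 + off_y : ys1 + off_y, xs0 + off_x : xs1 + off_x] = src[ys0:ys1, xs0:xs1]
    return MipImage(out, image.plane, image.source_extent, offset=(off_y, off_x))


def cutout_augment(image: MipImage, n_holes: int, hole_size: int, seed: int) -> MipImage:
    """Set ``n_holes`` random square regions to the image minimum (emulating
    bone destroyed by fracture or obscured by metal)."""
    if hole_size < 1:
        raise ValueError("hole_size must be >= 1")
    out = image.pixels.copy()
    if n_holes > 0:
        rng = np.random.default_rng(seed)
        fill = out.min()
        h, w = out.shape
        for _ in range(n_holes):
            cy = int(rng.integers(0, h))
            cx = int(rng.integers(0, w))
            half = hole_size // 2
            y0, y1 = max(0, cy - half), min(h, cy - half + hole_size)
            x0, x1 = max(0, cx - half), min(w, cx - half + hole_size)
            out[y0:y1, x0:x1] = fill
    return MipImage(out, image.plane, image.source_extent, image.offset)


def assemble_voi(coronal_roi: Roi2D, sagittal_roi: Roi2D) -> Voi3D:
    """Combine per-plane 2-D detections into a 3-D VOI.

    The coronal ROI supplies the x range, the sagittal ROI the y range, and z
    is the intersection of the two planes' z ranges (both see z).  Coronal ROI
    axes are (u=x, v=z); sagittal (u=y, v=z).
    """
    z0 = max(coronal_roi.v0, sagittal_roi.v0)
    z1 = min(coronal_roi.v1, sagittal_roi.v1)
    if z0 >= z1:
        raise ValueError("inconsistent ROIs: z ranges do not intersect")
    return Voi3D(coronal_roi.u0, coronal_roi.u1, sagittal_roi.u0, sagittal_roi.u1, z0, z1)


def make_propagation_label(mask_slices, index: int, window: int = 2) -> np.ndarray:
    """Propagation label for one slice from its neighbours' segmentations.

    The union U of the neighbouring slices' masks within ±window (the current
    slice excluded) is eroded by one pixel toward the current slice's extent:
    the result is erode(U) ∪ (U ∩ current).  Intact neighbours therefore fill
    regions the current slice has lost, while a slice consistent with its
    neighbours maps to itself.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    slices = [np.asarray(s, dtype=bool) for s in mask_slices]
    if not (0 <= index < len(slices)):
        raise ValueError("index out of range")
    current = slices[index]
    union = np.zeros_like(current)
    for j in range(max(0, index - window), min(len(slices), index + window + 1)):
        if j != index:
            union |= slices[j]
    if not union.any():
        return union
    eroded = ndimage.binary_erosion(union, structure=ndimage.generate_binary_structure(2, 1))
    return eroded | (union & current)
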