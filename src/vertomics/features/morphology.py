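"""Mask-based morphological features (IBSI conventions).

Volume and surface area come from a triangulated mesh of the mask (marching
cubes at the 0.5 isolevel); axis lengths from principal-component analysis of
voxel-centre coordinates (length along axis i = 4 * sqrt(lambda_i)).  Density
features relate the mesh volume/area to enclosing reference bodies.

Degenerate masks (single voxel, coplanar voxels) yield zero for ratios whose
reference body collapses; every feature stays finite.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage import measure

from ..volume import MaskVolume

_ELLIPSOID_P = 1.6075  # Thomsen's approximation exponent for ellipsoid area


def _mesh(mask: MaskVolume):
    padded = np.pad(mask.labels.astype(float), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=mask.spacing_mm)
    return verts, faces


def _mesh_volume(verts, faces) -> float:
    v0, v1, v2 = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    return float(abs(np.einsum("ij,ij->", v0, np.cross(v1, v2)) / 6.0))


def _ellipsoid_area(a: float, b: float, c: float) -> float:
    p = _ELLIPSOID_P
    term = ((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0
    return float(4.0 * np.pi * term ** (1.0 / p))


def _safe_div(num: float, den: float) -> float:
    return float(num / den) if den > 0 else 0.0


def morphological_features(mask: MaskVolume) -> dict[str, float]:
    if mask.count() == 0:
        raise ValueError("empty mask")
    spacing = np.asarray(mask.spacing_mm)
    idx = np.argwhere(mask.labels)
    coords = idx * spacing  # voxel centres in mm
    n = len(coords)

    approx_volume = n * mask.voxel_volume_mm3
    verts, faces = _mesh(mask)
    volume = _mesh_volume(verts, faces)
    area = float(measure.mesh_surface_area(verts, faces))

    # PCA axis lengths (population covariance)
    centred = coords - coords.mean(axis=0)
    cov = centred.T @ centred / n
    eigvals = np.sort(np.clip(np.linalg.eigvalsh(cov), 0.0, None))[::-1]
    major, minor, least = (4.0 * np.sqrt(eigvals)).tolist()

    # maximum 3-D diameter over convex-hull vertices (brute force fallback)
    try:
        hull = ConvexHull(coords)
        pts = coords[hull.vertices]
        hull_volume, hull_area = float(hull.volume), float(hull.area)
    except QhullError:
        pts = coords
        hull_volume, hull_area = 0.0, 0.0
    if len(pts) > 1:
        diffs = pts[:, None, :] - pts[None, :, :]
        max_diam = float(np.sqrt((diffs**2).sum(-1)).max())
    else:
        max_diam = 0.0

    # axis-aligned bounding box around voxel volumes
    extents = (idx.max(axis=0) - idx.min(axis=0) + 1) * spacing
    aabb_volume = float(np.prod(extents))
    aabb_area = float(2.0 * (extents[0] * extents[1] + extents[0] * extents[2] + extents[1] * extents[2]))

    r_equiv = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0) if volume > 0 else 0.0
    a_ell, b_ell, c_ell = 2.0 * np.sqrt(eigvals)
    aee_volume = 4.0 / 3.0 * np.pi * a_ell * b_ell * c_ell
    aee_area = _ellipsoid_area(a_ell, b_ell, c_ell) if aee_volume > 0 else 0.0

    return {
        "volume": volume,
        "approximate_volume": approx_volume,
        "surface_area": area,
        "surface_to_volume_ratio": _safe_div(area, volume),
        "compactness_1": _safe_div(volume, np.sqrt(np.pi) * area**1.5),
        "compactness_2": _safe_div(36.0 * np.pi * volume**2, area**3),
        "spherical_disproportion": _safe_div(area, 4.0 * np.pi * r_equiv**2),
        "sphericity": _safe_div((36.0 * np.pi * volume**2) ** (1.0 / 3.0), area),
        "asphericity": (_safe_div(area**3, 36.0 * np.pi * volume**2)) ** (1.0 / 3.0) - 1.0
        if volume > 0
        else 0.0,
        "maximum_3d_diameter": max_diam,
        "major_axis_length": major,
        "minor_axis_length": minor,
        "least_axis_length": least,
        "elongation": _safe_div(np.sqrt(eigvals[1]), np.sqrt(eigvals[0])),
        "flatness": _safe_div(np.sqrt(eigvals[2]), np.sqrt(eigvals[0])),
        "volume_density_aabb": _safe_div(volume, aabb_volume),
        "area_density_aabb": _safe_div(area, aabb_area),
        "volume_density_aee": _safe_div(volume, aee_volume),
        "area_density_aee": _safe_div(area, aee_area),
        "volume_density_convex_hull": _safe_div(volume, hull_volume),
        "area_density_convex_hull": _safe_div(area, hull_area),
    }
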