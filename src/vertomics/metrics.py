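"""Segmentation agreement metrics: Dice coefficient, cross-sectional-area
error, and average surface distance, plus cohort-level median/IQR summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import MaskVolume

# 6-connectivity: a surface voxel has at least one face-adjacent background voxel
_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class SegEvalResult:
    case_id: str
    label: str
    dsc: float
    csa_error_pct: float
    asd_mm: float


def _check_grids(auto: MaskVolume, truth: MaskVolume) -> None:
    if not auto.same_grid(truth):
        raise ValueError("masks are on different grids")


def dsc(auto: MaskVolume, truth: MaskVolume) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|)."""
    _check_grids(auto, truth)
    a, b = auto.labels, truth.labels
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        raise ValueError("undefined DSC: both masks empty")
    return float(2.0 * np.logical_and(a, b).sum() / (na + nb))


def csa_error(auto: MaskVolume, truth: MaskVolume) -> float:
    """Signed percent area difference ([B - A] / B) * 100.

    Positive when the automatic mask under-segments relative to the reference.
    Area is total cross-sectional area summed over axial slices (equivalently
    volume / slice thickness), giving one number per vertebra.
    """
    _check_grids(auto, truth)
    pixel_area = auto.spacing_mm[0] * auto.spacing_mm[1]
    area_a = float(auto.labels.sum()) * pixel_area
    area_b = float(truth.labels.sum()) * pixel_area
    if area_b == 0:
        raise ValueError("reference mask has zero area")
    return float((area_b - area_a) / area_b * 100.0)


def csa_error_per_slice(auto: MaskVolume, truth: MaskVolume) -> np.ndarray:
    """Per-axial-slice signed percent area difference (NaN where B is empty)."""
    _check_grids(auto, truth)
    a = auto.labels.sum(axis=(0, 1)).astype(float)
    b = truth.labels.sum(axis=(0, 1)).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(b > 0, (b - a) / b * 100.0, np.nan)


def surface_voxels(mask: MaskVolume) -> np.ndarray:
    """Boolean array marking mask voxels with >= 1 face-adjacent background voxel."""
    lab = mask.labels
    interior = ndimage.binary_erosion(lab, structure=_FACE_STRUCT, border_value=0)
    return lab & ~interior


def asd(auto: MaskVolume, truth: MaskVolume, symmetric: bool = False) -> float:
    """Average surface distance in mm (spacing-aware).

    Default is one-sided: the mean over A's surface voxels of the Euclidean
    distance to B's surface.  ``symmetric=True`` averages the two directions.
    """
    _check_grids(auto, truth)
    if auto.count() == 0 or truth.count() == 0:
        raise ValueError("ASD requires two nonempty masks")
    surf_a = surface_voxels(auto)
    surf_b = surface_voxels(truth)
    spacing = auto.spacing_mm

    def one_sided(src, dst):
        dist_to_dst = ndimage.distance_transform_edt(~dst, sampling=spacing)
        return float(dist_to_dst[src].mean())

    d_ab = one_sided(surf_a, surf_b)
    if not symmetric:
        return d_ab
    return 0.5 * (d_ab + one_sided(surf_b, surf_a))


def evaluate_case(auto: MaskVolume, truth: MaskVolume, case_id: str = "", label: str = "",
                  symmetric_asd: bool = False) -> SegEvalResult:
    return SegEvalResult(
        case_id=case_id,
        label=label,
        dsc=dsc(auto, truth),
        csa_error_pct=csa_error(auto, truth),
        asd_mm=asd(auto, truth, symmetric=symmetric_asd),
    )


def summarize_by_group(results, group_key: str = "label") -> pd.DataFrame:
    """Median and interquartile range per metric, overall and per group.

    Quartiles use linear interpolation (type-7), the numpy default.  Returns a
    tidy frame with columns group, metric, median, q1, q3, n.
    """
    if not results:
        raise ValueError("no results to summarize")
    df = pd.DataFrame([asdict(r) for r in results])
    metrics = ["dsc", "csa_error_pct", "asd_mm"]
    rows = []

    def summarize(sub: pd.DataFrame, name: str) -> None:
        for m in metrics:
            v = sub[m].to_numpy()
            rows.append(
                {
                    "group": name,
                    "metric": m,
                    "median": float(np.median(v)),
                    "q1": float(np.quantile(v, 0.25)),
                    "q3": float(np.quantile(v, 0.75)),
                    "n": len(v),
                }
            )

    summarize(df, "overall")
    for name, sub in df.groupby(group_key, sort=True):
        summarize(sub, str(name))
    return pd.DataFrame(rows)
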