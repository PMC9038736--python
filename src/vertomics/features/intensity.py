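"""Local-intensity, first-order statistical and intensity-histogram features.

Statistics use population moments (1/n), following IBSI.  The intensity
histogram operates on discretized levels 1..n_bins as produced by
``vertomics.volume.quantize_intensities``.  Ratio features whose denominator
vanishes on degenerate input are defined as 0 so every vector stays finite.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve

from ..volume import MaskVolume, VolumeGrid

PEAK_SPHERE_VOLUME_MM3 = 1000.0  # 1 cm^3 sphere, IBSI intensity-peak support


def _sphere_kernel(spacing) -> np.ndarray:
    radius = (3.0 * PEAK_SPHERE_VOLUME_MM3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    half = [int(np.floor(radius / s)) for s in spacing]
    axes = [np.arange(-h, h + 1) * s for h, s in zip(half, spacing)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    return (gx**2 + gy**2 + gz**2 <= radius**2).astype(float)


def local_intensity_features(volume: VolumeGrid, mask: MaskVolume) -> dict[str, float]:
    """IBSI local and global intensity peaks.

    The spherical mean at a voxel averages over all sphere voxels inside the
    image (zero beyond the boundary).  The local peak is the best spherical
    mean among global-maximum voxels; the global peak maximizes the spherical
    mean over every masked voxel.
    """
    if mask.count() == 0:
        raise ValueError("empty mask")
    kernel = _sphere_kernel(volume.spacing_mm)
    k = kernel.sum()
    means = fftconvolve(volume.intensities, kernel, mode="same") / k
    inside = mask.labels
    vals = volume.intensities[inside]
    vmax = vals.max()
    at_max = inside & (volume.intensities == vmax)
    return {
        "local_intensity_peak": float(means[at_max].max()),
        "global_intensity_peak": float(means[inside].max()),
    }


def _moments(x: np.ndarray) -> tuple[float, float, float, float]:
    mu = float(x.mean())
    var = float(x.var())
    if var == 0:
        return mu, 0.0, 0.0, 0.0
    sd = np.sqrt(var)
    skew = float(((x - mu) ** 3).mean() / sd**3)
    kurt = float(((x - mu) ** 4).mean() / var**2) - 3.0
    return mu, var, skew, kurt


def intensity_statistics(volume: VolumeGrid, mask: MaskVolume) -> dict[str, float]:
    if mask.count() == 0:
        raise ValueError("empty mask")
    x = volume.intensities[mask.labels]
    return statistics_from_values(x)


def statistics_from_values(x: np.ndarray) -> dict[str, float]:
    x = np.asarray(x, dtype=float)
    mu, var, skew, kurt = _moments(x)
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0
    qcd_den = p75 + p25
    return {
        "mean": mu,
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "median": float(p50),
        "minimum_gray_level": float(x.min()),
        "10th_percentile": float(p10),
        "25th_percentile": float(p25),
        "75th_percentile": float(p75),
        "90th_percentile": float(p90),
        "maximum_gray_level": float(x.max()),
        "interquartile_range": float(p75 - p25),
        "range": float(x.max() - x.min()),
        "mean_absolute_deviation": float(np.abs(x - mu).mean()),
        "robust_mean_absolute_deviation": rmad,
        "median_absolute_deviation": float(np.abs(x - p50).mean()),
        "coefficient_of_variation": float(np.sqrt(var) / mu) if mu != 0 else 0.0,
        "quartile_coefficient_of_dispersion": float((p75 - p25) / qcd_den)
        if qcd_den != 0
        else 0.0,
        "energy": float((x**2).sum()),
        "root_mean_square": float(np.sqrt((x**2).mean())),
    }


def intensity_histogram_features(levels: np.ndarray, mask: MaskVolume, n_bins: int = 64) -> dict[str, float]:
    """Histogram family on discretized levels 1..n_bins.

    Gradients use central differences over the n_bins-bin count histogram,
    one-sided at the ends; the reported gradient levels are the level at
    which the extremum occurs (lowest level on ties).
    """
    if mask.count() == 0:
        raise ValueError("empty mask")
    g = levels[mask.labels].astype(int)
    if g.min() < 1 or g.max() > n_bins:
        raise ValueError("levels outside 1..n_bins")
    out = statistics_from_values(g.astype(float))
    # the histogram family shares the first-order definitions, applied to levels
    rename = {
        "minimum_gray_level": "minimum",
        "maximum_gray_level": "maximum",
    }
    feats = {}
    keep = [
        "mean", "variance", "skewness", "kurtosis", "median",
        "minimum_gray_level", "10th_percentile", "90th_percentile",
        "maximum_gray_level", "interquartile_range", "range",
        "mean_absolute_deviation", "robust_mean_absolute_deviation",
        "median_absolute_deviation", "coefficient_of_variation",
        "quartile_coefficient_of_dispersion",
    ]
    for k in keep:
        feats[rename.get(k, k)] = out[k]

    counts = np.bincount(g, minlength=n_bins + 1)[1:].astype(float)
    p = counts / counts.sum()
    nz = p[p > 0]
    feats["mode"] = float(np.argmax(counts) + 1)
    feats["entropy"] = float(-(nz * np.log2(nz)).sum())
    feats["uniformity"] = float((p**2).sum())
    grad = np.gradient(counts)
    feats["maximum_histogram_gradient"] = float(grad.max())
    feats["maximum_histogram_gradient_level"] = float(np.argmax(grad) + 1)
    feats["minimum_histogram_gradient"] = float(grad.min())
    feats["minimum_histogram_gradient_level"] = float(np.argmin(grad) + 1)

    order = [
        "mean", "variance", "skewness", "kurtosis", "median", "minimum",
        "10th_percentile", "90th_percentile", "maximum", "mode",
        "interquartile_range", "range", "mean_absolute_deviation",
        "robust_mean_absolute_deviation", "median_absolute_deviation",
        "coefficient_of_variation", "quartile_coefficient_of_dispersion",
        "entropy", "uniformity", "maximum_histogram_gradient",
        "maximum_histogram_gradient_level", "minimum_histogram_gradient",
        "minimum_histogram_gradient_level",
    ]
    return {k: feats[k] for k in order}
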