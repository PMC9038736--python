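"""The 280-entry feature catalog.

The extractor computes ten IBSI feature families on the original image plus
local-intensity / statistical / histogram families on Laplacian-of-Gaussian
filtered images at three scales.  The exact manifest below is a fixed package
constant: texture-feature values depend on conventions (binning, neighbourhood,
aggregation), so the catalog pins names, families, image sources and order.

Composition (280 total):
    original image : morphology 21, local intensity 2, statistics 20,
                     intensity histogram 23, GLCM 25, GLRLM 16, GLSZM 16,
                     NGLDM 17, NGTDM 5                              = 145
    LoG sigma in {1, 2, 3} mm : local intensity 2, statistics 20,
                     intensity histogram 23   (45 per scale)        = 135
"""

from __future__ import annotations

from dataclasses import dataclass

MORPHOLOGY = [
    "volume",
    "approximate_volume",
    "surface_area",
    "surface_to_volume_ratio",
    "compactness_1",
    "compactness_2",
    "spherical_disproportion",
    "sphericity",
    "asphericity",
    "maximum_3d_diameter",
    "major_axis_length",
    "minor_axis_length",
    "least_axis_length",
    "elongation",
    "flatness",
    "volume_density_aabb",
    "area_density_aabb",
    "volume_density_aee",
    "area_density_aee",
    "volume_density_convex_hull",
    "area_density_convex_hull",
]

LOCAL_INTENSITY = [
    "local_intensity_peak",
    "global_intensity_peak",
]

STATISTICS = [
    "mean",
    "variance",
    "skewness",
    "kurtosis",
    "median",
    "minimum_gray_level",
    "10th_percentile",
    "25th_percentile",
    "75th_percentile",
    "90th_percentile",
    "maximum_gray_level",
    "interquartile_range",
    "range",
    "mean_absolute_deviation",
    "robust_mean_absolute_deviation",
    "median_absolute_deviation",
    "coefficient_of_variation",
    "quartile_coefficient_of_dispersion",
    "energy",
    "root_mean_square",
]

HISTOGRAM = [
    "mean",
    "variance",
    "skewness",
    "kurtosis",
    "median",
    "minimum",
    "10th_percentile",
    "90th_percentile",
    "maximum",
    "mode",
    "interquartile_range",
    "range",
    "mean_absolute_deviation",
    "robust_mean_absolute_deviation",
    "median_absolute_deviation",
    "coefficient_of_variation",
    "quartile_coefficient_of_dispersion",
    "entropy",
    "uniformity",
    "maximum_histogram_gradient",
    "maximum_histogram_gradient_level",
    "minimum_histogram_gradient",
    "minimum_histogram_gradient_level",
]

GLCM = [
    "joint_maximum",
    "joint_average",
    "joint_variance",
    "joint_entropy",
    "difference_average",
    "difference_variance",
    "difference_entropy",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "angular_second_moment",
    "contrast",
    "dissimilarity",
    "inverse_difference",
    "inverse_difference_normalized",
    "inverse_difference_moment",
    "inverse_difference_moment_normalized",
    "inverse_variance",
    "correlation",
    "autocorrelation",
    "cluster_tendency",
    "cluster_shade",
    "cluster_prominence",
    "information_correlation_1",
    "information_correlation_2",
]

GLRLM = [
    "short_runs_emphasis",
    "long_runs_emphasis",
    "low_gray_level_run_emphasis",
    "high_gray_level_run_emphasis",
    "short_run_low_gray_level_emphasis",
    "short_run_high_gray_level_emphasis",
    "long_run_low_gray_level_emphasis",
    "long_run_high_gray_level_emphasis",
    "gray_level_non_uniformity",
    "gray_level_non_uniformity_normalized",
    "run_length_non_uniformity",
    "run_length_non_uniformity_normalized",
    "run_percentage",
    "gray_level_variance",
    "run_length_variance",
    "run_entropy",
]

GLSZM = [
    "small_zone_emphasis",
    "large_zone_emphasis",
    "low_gray_level_zone_emphasis",
    "high_gray_level_zone_emphasis",
    "small_zone_low_gray_level_emphasis",
    "small_zone_high_gray_level_emphasis",
    "large_zone_low_gray_level_emphasis",
    "large_zone_high_gray_level_emphasis",
    "gray_level_non_uniformity",
    "gray_level_non_uniformity_normalized",
    "zone_size_non_uniformity",
    "zone_size_non_uniformity_normalized",
    "zone_percentage",
    "gray_level_variance",
    "zone_size_variance",
    "zone_size_entropy",
]

NGLDM = [
    "low_dependence_emphasis",
    "high_dependence_emphasis",
    "low_gray_level_count_emphasis",
    "high_gray_level_count_emphasis",
    "low_dependence_low_gray_level_emphasis",
    "low_dependence_high_gray_level_emphasis",
    "high_dependence_low_gray_level_emphasis",
    "high_dependence_high_gray_level_emphasis",
    "gray_level_non_uniformity",
    "gray_level_non_uniformity_normalized",
    "dependence_count_non_uniformity",
    "dependence_count_non_uniformity_normalized",
    "dependence_count_percentage",
    "gray_level_variance",
    "dependence_count_variance",
    "dependence_count_entropy",
    "dependence_count_energy",
]

NGTDM = [
    "coarseness",
    "contrast",
    "busyness",
    "complexity",
    "strength",
]

_FAMILY_PREFIX = {
    "morphology": "morph",
    "local_intensity": "locint",
    "statistics": "stat",
    "intensity_histogram": "ih",
    "glcm": "glcm",
    "glrlm": "glrlm",
    "glszm": "glszm",
    "ngldm": "ngldm",
    "ngtdm": "ngtdm",
}

DEFAULT_LOG_SIGMAS_MM = (1.0, 2.0, 3.0)


@dataclass(frozen=True)
class CatalogEntry:
    key: str  # unique column name, e.g. "log1mm_stat_75th_percentile"
    family: str
    name: str
    image_source: str  # "original" or "log_<sigma>mm"


def _source_prefix(source: str) -> str:
    if source == "original":
        return ""
    return source + "_"


def build_catalog(log_sigmas_mm=DEFAULT_LOG_SIGMAS_MM) -> list[CatalogEntry]:
    """Assemble the ordered feature catalog (280 entries at the defaults)."""
    entries: list[CatalogEntry] = []

    def add(family: str, names, source: str) -> None:
        prefix = _source_prefix(source) + _FAMILY_PREFIX[family] + "_"
        for n in names:
            entries.append(CatalogEntry(prefix + n, family, n, source))

    add("morphology", MORPHOLOGY, "original")
    add("local_intensity", LOCAL_INTENSITY, "original")
    add("statistics", STATISTICS, "original")
    add("intensity_histogram", HISTOGRAM, "original")
    add("glcm", GLCM, "original")
    add("glrlm", GLRLM, "original")
    add("glszm", GLSZM, "original")
    add("ngldm", NGLDM, "original")
    add("ngtdm", NGTDM, "original")
    for sigma in log_sigmas_mm:
        source = log_source_name(sigma)
        add("local_intensity", LOCAL_INTENSITY, source)
        add("statistics", STATISTICS, source)
        add("intensity_histogram", HISTOGRAM, source)

    keys = [e.key for e in entries]
    if len(keys) != len(set(keys)):
        raise RuntimeError("catalog keys are not unique")
    return entries


def log_source_name(sigma_mm: float) -> str:
    s = f"{sigma_mm:g}".replace(".", "p")
    return f"log{s}mm"


def catalog_keys(log_sigmas_mm=DEFAULT_LOG_SIGMAS_MM) -> list[str]:
    return [e.key for e in build_catalog(log_sigmas_mm)]
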