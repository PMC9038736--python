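import numpy as np
import pytest

from vertomics import MaskVolume, VolumeGrid
from vertomics.features import (
    FeatureConfig,
    build_catalog,
    extract_features,
    intensity_histogram_features,
    intensity_statistics,
    local_intensity_features,
    log_filter,
    morphological_features,
)

ISO = (1.0, 1.0, 1.0)


def vol(arr, spacing=ISO):
    return VolumeGrid(np.asarray(arr, dtype=float), spacing)


def mask_of(arr, spacing=ISO):
    return MaskVolume(np.asarray(arr, dtype=bool), spacing)


class TestCatalog:
    def test_exactly_280_unique_entries(self):
        cat = build_catalog()
        keys = [e.key for e in cat]
        assert len(cat) == 280
        assert len(set(keys)) == 280

    def test_signature_features_resolve(self):
        from vertomics import published_model

        keys = {e.key for e in build_catalog()}
        for name in published_model().feature_names:
            assert name in keys

    def test_all_ten_families_present(self):
        families = {(e.family, e.image_source != "original") for e in build_catalog()}
        original = {f for f, is_log in families if not is_log}
        filtered = {f for f, is_log in families if is_log}
        assert {
            "morphology", "local_intensity", "statistics", "intensity_histogram",
            "glcm", "glrlm", "glszm", "ngldm", "ngtdm",
        } <= original
        assert {"local_intensity", "statistics", "intensity_histogram"} == filtered


class TestMorphology:
    def test_approximate_volume_counts_voxels(self):
        arr = np.zeros((8, 8, 8), dtype=bool)
        arr[1:6, 1:6, 1:5] = True  # 100 voxels
        f = morphological_features(mask_of(arr))
        assert f["approximate_volume"] == pytest.approx(100.0)

    def test_single_voxel_axes_collapse(self):
        arr = np.zeros((5, 5, 5), dtype=bool)
        arr[2, 2, 2] = True
        f = morphological_features(mask_of(arr))
        assert f["major_axis_length"] == 0.0
        assert f["least_axis_length"] == 0.0
        assert f["maximum_3d_diameter"] == 0.0

    def test_ball_axis_length_closed_form(self):
        # uniform ball of radius r: covariance r^2/5 per axis, axis = 4r/sqrt(5)
        r = 10.0
        n = 25
        c = (n - 1) / 2
        g = np.arange(n)
        xx, yy, zz = np.meshgrid(g, g, g, indexing="ij")
        ball = (xx - c) ** 2 + (yy - c) ** 2 + (zz - c) ** 2 <= r**2
        f = morphological_features(mask_of(ball))
        expected = 4.0 * r / np.sqrt(5.0)
        assert f["major_axis_length"] == pytest.approx(expected, rel=0.05)
        # marching cubes on binary data overestimates the smooth sphere's area
        assert 0.85 < f["sphericity"] <= 1.001
        assert f["maximum_3d_diameter"] == pytest.approx(2 * r, rel=0.07)

    def test_mesh_volume_close_to_voxel_volume(self):
        arr = np.zeros((10, 10, 10), dtype=bool)
        arr[2:8, 2:8, 2:8] = True
        f = morphological_features(mask_of(arr, spacing=(0.5, 0.5, 1.0)))
        assert f["volume"] == pytest.approx(f["approximate_volume"], rel=0.15)

    def test_all_features_finite_on_plane(self):
        arr = np.zeros((6, 6, 6), dtype=bool)
        arr[2, 1:5, 1:5] = True  # coplanar voxels: degenerate hull
        f = morphological_features(mask_of(arr))
        assert all(np.isfinite(v) for v in f.values())


class TestLocalIntensity:
    def test_constant_volume_peaks_equal_constant(self):
        arr = np.full((30, 30, 30), 42.0)
        m = np.zeros_like(arr, dtype=bool)
        m[10:20, 10:20, 10:20] = True
        f = local_intensity_features(vol(arr), mask_of(m))
        assert f["local_intensity_peak"] == pytest.approx(42.0, rel=1e-6)
        assert f["global_intensity_peak"] == pytest.approx(42.0, rel=1e-6)

    def test_single_bright_voxel_sphere_mean(self):
        arr = np.zeros((31, 31, 31))
        arr[15, 15, 15] = 1000.0
        m = np.ones_like(arr, dtype=bool)
        f = local_intensity_features(vol(arr), mask_of(m))
        # independent count of voxel centres inside the 1 cm^3 sphere
        radius = (3.0 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
        g = np.arange(-8, 9)
        xx, yy, zz = np.meshgrid(g, g, g, indexing="ij")
        n = int((xx**2 + yy**2 + zz**2 <= radius**2).sum())
        assert f["local_intensity_peak"] == pytest.approx(1000.0 / n, rel=1e-6)

    def test_global_peak_dominates_local(self):
        rng = np.random.default_rng(0)
        arr = rng.normal(size=(20, 20, 20))
        m = np.zeros_like(arr, dtype=bool)
        m[4:16, 4:16, 4:16] = True
        f = local_intensity_features(vol(arr), mask_of(m))
        assert f["global_intensity_peak"] >= f["local_intensity_peak"] - 1e-12


class TestStatisticsAndHistogram:
    def test_tiny_sample_statistics(self):
        arr = np.zeros((3, 3, 3))
        m = np.zeros((3, 3, 3), dtype=bool)
        arr[0, 0, :3] = [1.0, 2.0, 3.0]
        m[0, 0, :3] = True
        f = intensity_statistics(vol(arr), mask_of(m))
        assert f["minimum_gray_level"] == 1.0
        assert f["mean"] == 2.0
        assert f["maximum_gray_level"] == 3.0
        assert f["energy"] == 14.0

    def test_constant_histogram_entropy_zero_uniformity_one(self):
        levels = np.zeros((4, 4, 4), dtype=int)
        m = np.zeros((4, 4, 4), dtype=bool)
        m[1:3, 1:3, 1:3] = True
        levels[m] = 17
        f = intensity_histogram_features(levels, mask_of(m))
        assert f["entropy"] == 0.0
        assert f["uniformity"] == 1.0

    def test_two_spike_histogram_gradient_location(self):
        # 50 voxels at level 1 and 50 at level 64: the steepest rise/fall sit
        # next to the occupied bins
        levels = np.zeros((5, 5, 4), dtype=int)
        m = np.ones((5, 5, 4), dtype=bool)
        flat = levels.reshape(-1)
        flat[:50] = 1
        flat[50:] = 64
        f = intensity_histogram_features(levels, mask_of(m))
        assert f["maximum_histogram_gradient_level"] in (1.0, 2.0, 63.0, 64.0)
        assert f["minimum_histogram_gradient_level"] in (1.0, 2.0, 63.0, 64.0)
        assert f["maximum_histogram_gradient"] > 0 > f["minimum_histogram_gradient"]


class TestLogFilter:
    def test_constant_input_zero_response(self):
        out = log_filter(vol(np.full((10, 10, 10), 123.0)), 2.0)
        np.testing.assert_allclose(out.intensities, 0.0, atol=1e-9)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        arr = rng.normal(size=(12, 12, 12))
        a = log_filter(vol(3.0 * arr), 1.5).intensities
        b = 3.0 * log_filter(vol(arr), 1.5).intensities
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_blob_scale_selectivity(self):
        # a Gaussian blob of scale sigma responds strongest near matching sigma
        sigma_blob = 3.0
        g = np.arange(41) - 20.0
        xx, yy, zz = np.meshgrid(g, g, g, indexing="ij")
        blob = np.exp(-(xx**2 + yy**2 + zz**2) / (2 * sigma_blob**2))
        responses = {}
        for s in (1.0, 3.0, 9.0):
            out = log_filter(vol(blob), s).intensities
            responses[s] = abs(out[20, 20, 20]) * s**2  # scale-normalized
        assert responses[3.0] > responses[1.0]
        assert responses[3.0] > responses[9.0]


@pytest.fixture(scope="module")
def native_vector(malignant_phantom):
    cfg = FeatureConfig(resample_spacing_mm=None)
    return extract_features(malignant_phantom.volume, malignant_phantom.truth_mask, cfg)


class TestExtraction:
    def test_exactly_280_finite_values(self, native_vector):
        assert len(native_vector) == 280
        assert np.isfinite(native_vector.values.to_numpy()).all()

    def test_catalog_order(self, native_vector):
        assert list(native_vector.values.index) == [e.key for e in build_catalog()]

    def test_deterministic(self, malignant_phantom, native_vector):
        cfg = FeatureConfig(resample_spacing_mm=None)
        again = extract_features(
            malignant_phantom.volume, malignant_phantom.truth_mask, cfg
        )
        np.testing.assert_array_equal(
            again.values.to_numpy(), native_vector.values.to_numpy()
        )

    def test_hu_shift_moves_mean_not_morphology(self, malignant_phantom, native_vector):
        cfg = FeatureConfig(resample_spacing_mm=None)
        shifted = VolumeGrid(
            malignant_phantom.volume.intensities + 100.0,
            malignant_phantom.volume.spacing_mm,
        )
        fv = extract_features(shifted, malignant_phantom.truth_mask, cfg)
        assert fv.values["stat_mean"] == pytest.approx(
            native_vector.values["stat_mean"] + 100.0, abs=1e-6
        )
        for key in ("morph_approximate_volume", "morph_major_axis_length", "morph_sphericity"):
            assert fv.values[key] == pytest.approx(native_vector.values[key], rel=1e-12)

    def test_empty_mask_rejected(self, malignant_phantom):
        empty = MaskVolume(
            np.zeros(malignant_phantom.volume.shape, dtype=bool),
            malignant_phantom.volume.spacing_mm,
        )
        with pytest.raises(ValueError):
            extract_features(malignant_phantom.volume, empty)
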