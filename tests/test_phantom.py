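import numpy as np
import pytest
from dataclasses import replace

from vertomics import (
    PhantomParams,
    asd,
    dsc,
    make_cohort,
    make_vertebra_phantom,
    select_one_vertebra_per_patient,
    simulate_observer_mask,
)


class TestMakeVertebraPhantom:
    def test_same_params_and_seed_bitwise_identical(self, default_params):
        a = make_vertebra_phantom(default_params, "malignant")
        b = make_vertebra_phantom(default_params, "malignant")
        np.testing.assert_array_equal(a.volume.intensities, b.volume.intensities)
        np.testing.assert_array_equal(a.truth_mask.labels, b.truth_mask.labels)

    def test_malignant_darker_than_acute_benign(self, default_params, benign_phantom, malignant_phantom):
        p = default_params
        mean_b = benign_phantom.volume.intensities[benign_phantom.truth_mask.labels].mean()
        mean_m = malignant_phantom.volume.intensities[malignant_phantom.truth_mask.labels].mean()
        lesion_vol = 4.0 / 3.0 * np.pi * p.lesion_radius_mm**3
        body_vol = malignant_phantom.truth_mask.count() * malignant_phantom.truth_mask.voxel_volume_mm3
        bound = (p.trabecular_mean_hu - p.lesion_mean_hu) * (lesion_vol / body_vol) / 2.0
        assert mean_b - mean_m >= bound

    def test_noise_free_interior_is_constant(self):
        p = PhantomParams(
            fracture_compression_frac=0.0,
            noise_sd_hu=0.0,
            trabecular_sd_hu=0.0,
            sclerosis_band_hu=0.0,
        )
        case = make_vertebra_phantom(p, "benign_acute")
        interior_vals = np.unique(
            case.volume.intensities[
                case.truth_mask.labels
                & (case.volume.intensities != p.cortical_mean_hu)
            ]
        )
        assert interior_vals.tolist() == [p.trabecular_mean_hu]

    def test_cortical_shell_present(self, benign_phantom, default_params):
        shell_frac = (
            benign_phantom.volume.intensities[benign_phantom.truth_mask.labels]
            > default_params.cortical_mean_hu - 100
        ).mean()
        assert 0.1 < shell_frac < 0.9

    def test_lesion_too_large_rejected(self, default_params):
        p = replace(default_params, lesion_radius_mm=50.0)
        with pytest.raises(ValueError, match="lesion exceeds body"):
            make_vertebra_phantom(p, "malignant")

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            PhantomParams(voxel_spacing_mm=(0.5, -0.5, 1.0))
        with pytest.raises(ValueError):
            PhantomParams(fracture_compression_frac=1.0)

    def test_unknown_label_rejected(self, default_params):
        with pytest.raises(ValueError):
            make_vertebra_phantom(default_params, "intact")

    def test_compression_reduces_height(self, default_params):
        tall = make_vertebra_phantom(
            replace(default_params, fracture_compression_frac=0.0), "benign_chronic"
        )
        short = make_vertebra_phantom(
            replace(default_params, fracture_compression_frac=0.4), "benign_chronic"
        )
        z_extent = lambda c: np.ptp(np.nonzero(c.truth_mask.labels.any(axis=(0, 1)))[0])
        assert z_extent(short) < z_extent(tall)


class TestObserverMask:
    def test_zero_displacement_is_identity(self, benign_phantom):
        out = simulate_observer_mask(benign_phantom.truth_mask, 0.0, 99)
        np.testing.assert_array_equal(out.labels, benign_phantom.truth_mask.labels)

    def test_asd_bounded_by_displacement(self, benign_phantom):
        truth = benign_phantom.truth_mask
        out = simulate_observer_mask(truth, 1.0, 5)
        assert asd(out, truth, symmetric=True) <= 1.0

    def test_two_seeds_distinct_and_high_overlap(self, benign_phantom):
        truth = benign_phantom.truth_mask
        a = simulate_observer_mask(truth, 1.0, 1)
        b = simulate_observer_mask(truth, 1.0, 2)
        assert (a.labels != b.labels).any()
        assert dsc(a, truth) > 0.8
        assert dsc(b, truth) > 0.8

    def test_hausdorff_bound_on_small_grid(self):
        from scipy import ndimage

        arr = np.zeros((24, 24, 24), dtype=bool)
        arr[6:18, 6:18, 6:18] = True
        from vertomics import MaskVolume

        truth = MaskVolume(arr, (1.0, 1.0, 1.0))
        disp = 2.0
        out = simulate_observer_mask(truth, disp, 3)
        changed = out.labels ^ truth.labels
        if changed.any():
            # every flipped voxel lies within the displacement of the old boundary
            dist_to_surface = np.where(
                truth.labels,
                ndimage.distance_transform_edt(truth.labels),
                ndimage.distance_transform_edt(~truth.labels),
            )
            assert dist_to_surface[changed].max() <= disp + 1e-9

    def test_topology_single_component(self, benign_phantom):
        from scipy import ndimage

        out = simulate_observer_mask(benign_phantom.truth_mask, 2.0, 7)
        _, n = ndimage.label(out.labels)
        assert n == 1

    def test_empty_mask_rejected(self):
        from vertomics import MaskVolume

        empty = MaskVolume(np.zeros((5, 5, 5), dtype=bool), (1.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            simulate_observer_mask(empty, 1.0, 0)


SMALL = PhantomParams(grid_shape=(48, 48, 40), body_semi_axes_mm=(8.0, 6.0, 14.0), lesion_radius_mm=3.5)


class TestCohort:
    def test_empty_cohort(self):
        assert make_cohort(0, 0, SMALL, seed=1) == []

    def test_determinism_and_counts(self):
        a = make_cohort(4, 3, SMALL, seed=1, n_observers=1)
        b = make_cohort(4, 3, SMALL, seed=1, n_observers=1)
        assert len(a) == 7
        labels = [c.label for c in a]
        assert labels.count("malignant") == 3
        for ca, cb in zip(a, b):
            assert ca.patient_id == cb.patient_id
            np.testing.assert_array_equal(ca.volume.intensities, cb.volume.intensities)
            np.testing.assert_array_equal(
                ca.observer_masks[0].labels, cb.observer_masks[0].labels
            )

    def test_observer_masks_overlap_truth(self):
        cases = make_cohort(2, 2, SMALL, seed=3, n_observers=2, observer_displacement_mm=0.5)
        for c in cases:
            for om in c.observer_masks:
                assert dsc(om, c.truth_mask) > 0.8

    def test_patients_own_one_to_three_vertebrae(self):
        cases = make_cohort(10, 10, SMALL, seed=5, n_observers=0)
        counts = {}
        for c in cases:
            counts[c.patient_id] = counts.get(c.patient_id, 0) + 1
        assert set(counts.values()) <= {1, 2, 3}
        assert max(counts.values()) > 1  # multi-vertebra patients exist

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            make_cohort(-1, 0, SMALL, seed=0)


class TestSelectOnePerPatient:
    def _cases(self, layout, seed=0):
        """layout: dict patient -> number of vertebrae (tiny phantom reused)."""
        base = make_vertebra_phantom(SMALL, "benign_acute")
        out = []
        for pid, k in layout.items():
            for v in range(k):
                out.append(
                    type(base)(
                        base.volume, base.truth_mask, (), "benign_acute", pid, f"V{v + 1}"
                    )
                )
        return out

    def test_identity_when_single_vertebra_each(self):
        cases = self._cases({"P1": 1, "P2": 1, "P3": 1})
        out = select_one_vertebra_per_patient(cases, seed=4)
        assert [(c.patient_id, c.vertebra_id) for c in out] == [
            ("P1", "V1"),
            ("P2", "V1"),
            ("P3", "V1"),
        ]

    def test_one_case_per_patient(self):
        cases = self._cases({"P1": 2, "P2": 2, "P3": 2})
        out = select_one_vertebra_per_patient(cases, seed=4)
        assert len(out) == 3
        assert len({c.patient_id for c in out}) == 3

    def test_uniform_selection_frequency(self):
        cases = self._cases({"P1": 2})
        picks = [
            select_one_vertebra_per_patient(cases, seed=s)[0].vertebra_id
            for s in range(10_000)
        ]
        frac_v1 = picks.count("V1") / len(picks)
        assert abs(frac_v1 - 0.5) <= 0.02
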