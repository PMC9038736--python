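import numpy as np
import pandas as pd
import pytest

from vertomics import (
    apply_standardizer,
    correlation_prune,
    drop_zero_variance,
    fit_standardizer,
    lasso_cv_fit,
    lin_ccc,
    run_cascade,
    stability_filter,
)


def table(arr, names=None):
    arr = np.asarray(arr, dtype=float)
    names = names or [f"f{i}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, columns=names)


class TestZeroVariance:
    def test_constant_feature_dropped(self):
        t = table(np.column_stack([np.ones(5), np.arange(5)]), ["const", "varying"])
        out, report = drop_zero_variance(t)
        assert list(out.columns) == ["varying"]
        assert report.dropped[0][0] == "const"

    def test_no_constants_identity(self):
        rng = np.random.default_rng(0)
        t = table(rng.normal(size=(6, 4)))
        out, _ = drop_zero_variance(t)
        pd.testing.assert_frame_equal(out, t)

    def test_five_of_twenty_constant(self):
        rng = np.random.default_rng(1)
        arr = rng.normal(size=(10, 20))
        arr[:, [2, 5, 9, 13, 19]] = 7.0
        out, report = drop_zero_variance(table(arr))
        assert out.shape[1] == 15
        assert report.n_after_zero_variance == 15

    def test_rounding_catches_float_noise_constants(self):
        vals = 1.0 + np.array([0.0, 1e-15, -1e-15, 2e-15])
        out, _ = drop_zero_variance(table(vals[:, None], ["almost_const"]))
        assert out.shape[1] == 0


class TestStandardizer:
    def test_self_application_centres_and_scales(self):
        rng = np.random.default_rng(2)
        t = table(rng.normal(5, 3, size=(30, 4)))
        params = fit_standardizer(t)
        z = apply_standardizer(t, params)
        assert np.abs(z.mean().to_numpy()).max() < 1e-12
        np.testing.assert_allclose(z.std(ddof=1).to_numpy(), 1.0, rtol=1e-12)

    def test_test_row_at_training_mean_maps_to_zero(self):
        t = table([[1.0, 10.0], [2.0, 20.0], [3.0, 30.0]])
        params = fit_standardizer(t)
        z = apply_standardizer(table([[2.0, 20.0]]), params)
        np.testing.assert_allclose(z.to_numpy(), 0.0, atol=1e-14)

    def test_sample_sd_denominator(self):
        t = table([[1.0], [2.0], [3.0]])  # sample SD (n-1) = 1
        params = fit_standardizer(t)
        z = apply_standardizer(table([[4.0]]), params)
        assert z.iloc[0, 0] == pytest.approx(2.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            fit_standardizer(table(np.ones((4, 1))))


class TestLinCcc:
    def test_perfect_agreement(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert lin_ccc(x, x) == pytest.approx(1.0)

    def test_perfect_reversal(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        assert lin_ccc(x, -x) == pytest.approx(-1.0)

    def test_shifted_sequence_worked_example(self):
        # x=(1,2,3), y=(2,3,4): population moments give 2*(2/3)/((2/3)+(2/3)+1)
        assert lin_ccc([1, 2, 3], [2, 3, 4]) == pytest.approx(0.5714, abs=1e-4)

    def test_degenerate_rules(self):
        assert lin_ccc([2, 2, 2], [2, 2, 2]) == 1.0
        assert lin_ccc([2, 2, 2], [3, 3, 3]) == 0.0
        assert lin_ccc([2, 2, 2], [1, 2, 3]) == 0.0

    def test_bounded_by_pearson(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.normal(size=30)
            y = 0.5 * x + rng.normal(size=30) + rng.uniform(-2, 2)
            r = np.corrcoef(x, y)[0, 1]
            assert abs(lin_ccc(x, y)) <= abs(r) + 1e-12


class TestStabilityFilter:
    def _tables(self, n=35, p=6, seed=0):
        rng = np.random.default_rng(seed)
        primary = table(rng.normal(size=(n, p)))
        reps = [primary + rng.normal(0, 0.01, size=(n, p)) for _ in range(3)]
        return primary, [table(r.to_numpy(), list(primary.columns)) for r in reps]

    def test_identical_repeats_retain_all(self):
        primary, _ = self._tables()
        out, report = stability_filter(primary, [primary.copy()] * 3)
        assert list(out.columns) == list(primary.columns)

    def test_noise_replaced_feature_dropped(self):
        primary, reps = self._tables(seed=4)
        rng = np.random.default_rng(5)
        reps[1]["f2"] = rng.normal(size=len(primary))  # independent noise
        out, report = stability_filter(primary, reps)
        assert "f2" not in out.columns
        assert report.ccc["f2"] < 0.5
        assert out.shape[1] == primary.shape[1] - 1

    def test_vacuous_threshold_keeps_everything(self):
        primary, reps = self._tables(seed=6)
        rng = np.random.default_rng(7)
        for r in reps:
            r["f0"] = rng.normal(size=len(primary))
        out, _ = stability_filter(primary, reps, threshold=-1.0)
        assert list(out.columns) == list(primary.columns)

    def test_unknown_cases_rejected(self):
        primary, reps = self._tables()
        bad = reps[0].copy()
        bad.index = bad.index + 1000
        with pytest.raises(ValueError):
            stability_filter(primary, [bad])


class TestCorrelationPrune:
    def test_uncorrelated_identity(self):
        rng = np.random.default_rng(8)
        t = table(rng.normal(size=(40, 5)))
        y = rng.integers(0, 2, size=40)
        out, _ = correlation_prune(t, y)
        assert list(out.columns) == list(t.columns)

    def test_duplicate_column_keeps_exactly_one(self):
        rng = np.random.default_rng(9)
        base = rng.normal(size=40)
        t = table(np.column_stack([base, base]), ["a", "a_copy"])
        y = rng.integers(0, 2, size=40)
        out, _ = correlation_prune(t, y)
        assert out.shape[1] == 1

    def test_weaker_association_dropped(self):
        rng = np.random.default_rng(10)
        y = np.repeat([0, 1], 30)
        a = y * 2.0 + rng.normal(0, 0.5, size=60)  # clean signal
        b = a + rng.normal(0, 0.35, size=60)  # corrupted copy (still |r|>0.9)
        c = rng.normal(size=60)  # independent
        t = table(np.column_stack([a, b, c]), ["a", "b", "c"])
        assert abs(np.corrcoef(a, b)[0, 1]) > 0.9
        out, report = correlation_prune(t, y)
        assert list(out.columns) == ["a", "c"]

    def test_no_retained_pair_above_threshold(self):
        rng = np.random.default_rng(11)
        base = rng.normal(size=(50, 3))
        noisy = np.hstack([base + rng.normal(0, 0.05, size=(50, 3)) for _ in range(3)])
        t = table(np.hstack([base, noisy]))
        y = rng.integers(0, 2, size=50)
        out, _ = correlation_prune(t, y, r_threshold=0.9)
        corr = np.corrcoef(out.to_numpy(), rowvar=False)
        off = np.abs(corr[~np.eye(out.shape[1], dtype=bool)])
        assert off.max() <= 0.9 + 1e-12


class TestLassoCv:
    def _planted(self, n=150, p=30, seed=12):
        # two informative features whose class means differ by 2 SD; the rest
        # are pure decoys
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(n, p))
        y = np.repeat([0, 1], [n // 2, n - n // 2])
        x[:, 0] += 2.0 * y
        x[:, 1] -= 2.0 * y
        return table(x), y

    def test_null_limit_gives_empty_support(self):
        rng = np.random.default_rng(13)
        x = table(rng.normal(size=(60, 5)))
        y = np.repeat([0, 1], [20, 40])
        spec = lasso_cv_fit(x, y, seed=1, n_lambdas=1)  # grid = {lambda_max}
        assert spec.feature_names == ()
        # unpenalized-intercept MLE would be logit(2/3); liblinear shrinks a
        # touch, so compare loosely
        assert spec.intercept == pytest.approx(np.log(2.0), abs=0.2)

    def test_planted_support_recovered(self):
        x, y = self._planted()
        spec = lasso_cv_fit(x, y, seed=3)
        assert "f0" in spec.feature_names and "f1" in spec.feature_names
        decoys = [f for f in spec.feature_names if f not in ("f0", "f1")]
        assert len(decoys) <= 0.2 * (x.shape[1] - 2)

    def test_seed_determinism(self):
        x, y = self._planted(seed=14)
        a = lasso_cv_fit(x, y, seed=9)
        b = lasso_cv_fit(x, y, seed=9)
        assert a.feature_names == b.feature_names
        np.testing.assert_allclose(a.coefficients, b.coefficients)

    def test_single_class_rejected(self):
        rng = np.random.default_rng(15)
        with pytest.raises(ValueError):
            lasso_cv_fit(table(rng.normal(size=(20, 3))), np.zeros(20, dtype=int), seed=0)


class TestCascade:
    def test_stagewise_removal_of_planted_defects(self):
        rng = np.random.default_rng(16)
        n = 60
        y = np.repeat([0, 1], n // 2)
        signal = y * 2.0 + rng.normal(0, 0.8, size=n)
        informative = signal
        duplicate = signal + rng.normal(0, 1e-3, size=n)
        constant = np.full(n, 3.0)
        unstable = rng.normal(size=n)
        decoy = rng.normal(size=n)
        t = table(
            np.column_stack([informative, duplicate, constant, unstable, decoy]),
            ["informative", "duplicate", "constant", "unstable", "decoy"],
        )
        # repeats agree everywhere except the unstable feature
        reps = []
        for k in range(3):
            r = t.drop(columns="constant")
            r = r + rng.normal(0, 1e-6, size=r.shape)
            r["unstable"] = rng.normal(size=n)
            r["constant"] = constant
            reps.append(r)
        spec, params, report = run_cascade(t, y, reps, seed=2)
        stages = {name: stage for name, stage, _ in report.dropped}
        assert stages["constant"] == "zero_variance"
        assert stages["unstable"] == "stability"
        assert stages["duplicate"] == "correlation"
        assert "informative" in spec.feature_names
        assert (
            report.n_initial
            >= report.n_after_zero_variance
            >= report.n_after_stability
            >= report.n_after_correlation
            >= report.n_after_lasso
        )

    def test_model_carries_standardization(self):
        rng = np.random.default_rng(17)
        n = 40
        y = np.repeat([0, 1], n // 2)
        x = rng.normal(size=(n, 6))
        x[:, 0] += y * 3.0
        t = table(x)
        spec, params, report = run_cascade(t, y, seed=5)
        assert spec.standardization_mean is not None
        assert set(spec.standardization_mean.index) == set(spec.feature_names)
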