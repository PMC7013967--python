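import numpy as np
import pytest

from wristrig.model import (
    BaselineGatedCalibration,
    RigidityCalibration,
    RigidityModelFile,
    class_means,
    fit_quadratic,
    loocv_training_error,
)

from oracles import oracle_loocv, quad_fit_normal_equations


class TestClassMeans:
    def test_hand_means(self):
        labels, means = class_means([2, 4, 6, 8], [0, 0, 40, 40])
        assert np.array_equal(labels, [0, 40])
        assert np.array_equal(means, [3, 7])

    def test_single_window_classes(self):
        labels, means = class_means([5.0, 9.0], [0, 80])
        assert np.array_equal(means, [5.0, 9.0])

    def test_invalid_windows_do_not_shift_means(self):
        _, base = class_means([2, 4], [0, 0])
        _, with_junk = class_means(
            [2, 4, 1000.0], [0, 0, 0], valid=[True, True, False]
        )
        assert np.array_equal(base, with_junk)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            class_means([], [])


class TestQuadraticFit:
    def test_exact_three_point_interpolation(self):
        x = np.array([1.0, 2.0, 3.0])
        y = 0.1 * x**2 + x + 5
        coef, resid = fit_quadratic(x, y)
        assert np.allclose(coef, [0.1, 1.0, 5.0], atol=1e-9)
        assert np.allclose(resid, 0, atol=1e-9)

    def test_noiseless_six_points_zero_residual(self):
        x = np.linspace(1, 10, 6)
        y = -0.5 * x**2 + 9 * x - 3
        _, resid = fit_quadratic(x, y)
        assert np.allclose(resid, 0, atol=1e-8)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        x = np.sort(rng.uniform(0, 20, 6))
        y = 0.3 * x**2 - 2 * x + 40 + rng.normal(0, 3, 6)
        coef, _ = fit_quadratic(x, y)
        assert np.allclose(coef, quad_fit_normal_equations(x, y), rtol=1e-7)

    def test_degenerate_designs_raise(self):
        with pytest.raises(ValueError):
            fit_quadratic([1.0, 2.0], [0, 40])
        with pytest.raises(ValueError):
            fit_quadratic([3.0, 3.0, 3.0], [0, 40, 80])


class TestCalibration:
    def test_linear_model_evaluation_and_clamping(self):
        est = RigidityCalibration(class_set=(0, 40, 50, 60, 70, 80))
        est.coef_ = np.array([0.0, 10.0, 0.0])
        est.class_labels_ = np.array([0.0])
        assert est.predict([5.0])[0] == 50.0
        assert est.predict([100.0])[0] == 80.0  # clamps above
        assert est.predict([-3.0])[0] == 0.0  # clamps below

    def test_noiseless_class_means_predict_their_labels(self):
        """When class means lie exactly on a quadratic, each mean maps back
        to its own label."""
        classes = np.array([0, 40, 50, 60, 70, 80], dtype=float)
        phi = np.sqrt(classes + 4.0)  # labels = phi^2 - 4 exactly
        est = RigidityCalibration().fit(phi, classes)
        assert np.allclose(est.predict(phi), classes, atol=1e-8)

    def test_label_outside_class_set_rejected(self):
        with pytest.raises(ValueError, match="class set"):
            RigidityCalibration(class_set=(0, 40)).fit([1, 2], [0, 35])

    def test_scale_consistency(self):
        """Scaling descriptors by k and refitting predicts identically."""
        rng = np.random.default_rng(8)
        labels = np.repeat([0, 40, 50, 60, 70, 80], 10)
        phi = 1.0 + labels / 20.0 + rng.normal(0, 0.1, labels.size)
        a = RigidityCalibration().fit(phi, labels)
        k = 37.5
        b = RigidityCalibration().fit(k * phi, labels)
        probe = np.linspace(phi.min(), phi.max(), 13)
        assert np.allclose(a.predict(probe), b.predict(k * probe), atol=1e-6)

    def test_classify_invalid_window(self):
        est = RigidityCalibration()
        est.coef_ = np.array([0.0, 1.0, 0.0])
        assert est.classify(5.0, valid=False) is None

    def test_sklearn_get_set_params_round_trip(self):
        est = RigidityCalibration(class_set=(0, 40, 80))
        clone = RigidityCalibration(**est.get_params())
        assert clone.get_params() == est.get_params()


class TestBaselineGating:
    @pytest.fixture
    def gated(self):
        rng = np.random.default_rng(10)
        labels = np.tile(np.repeat([0, 40, 50, 60, 70, 80], 8), 2)
        updrs = np.concatenate([np.full(48, 2), np.full(48, 3)])
        phi = np.where(updrs <= 2, 2.0, 1.0) + labels / 15.0 + rng.normal(0, 0.05, 96)
        return BaselineGatedCalibration().fit(phi, labels, baseline_updrs=updrs)

    def test_low_regime_selection(self, gated):
        assert gated.select_model(1) is gated.low_model_
        assert gated.select_model(2) is gated.low_model_

    def test_high_regime_selection(self, gated):
        assert gated.select_model(3) is gated.high_model_

    def test_updrs_4_unsupported(self, gated):
        with pytest.raises(ValueError, match="UPDRS 4"):
            gated.select_model(4)

    def test_missing_regime_rejected_at_fit(self):
        with pytest.raises(ValueError, match="regime"):
            BaselineGatedCalibration().fit(
                [1, 2, 3], [0, 40, 80], baseline_updrs=[3, 3, 3]
            )


class TestLoocv:
    def test_perfect_quadratic_gives_zero_error(self):
        labels = np.repeat([0.0, 40, 50, 60, 70, 80], 4)
        phi = np.sqrt(labels + 10.0)  # labels = phi^2 - 10 exactly
        res = loocv_training_error(phi, labels)
        assert res.mean_error == pytest.approx(0.0, abs=1e-8)
        assert res.sd_error == pytest.approx(0.0, abs=1e-8)

    def test_exhaustive_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(21)
        labels = np.repeat([0.0, 40, 50, 60, 70, 80], 3)
        phi = 1 + labels / 12.0 + rng.normal(0, 0.3, labels.size)
        res = loocv_training_error(phi, labels)
        mean, sd, skipped = oracle_loocv(phi, labels)
        assert res.mean_error == pytest.approx(mean, rel=1e-9)
        assert res.sd_error == pytest.approx(sd, rel=1e-9)
        assert res.n_skipped == skipped

    def test_exhaustive_is_permutation_invariant(self):
        rng = np.random.default_rng(22)
        labels = np.repeat([0.0, 40, 60, 80], 5)
        phi = labels / 10.0 + rng.normal(0, 0.2, labels.size)
        base = loocv_training_error(phi, labels)
        perm = rng.permutation(labels.size)
        shuffled = loocv_training_error(phi[perm], labels[perm])
        assert shuffled.mean_error == pytest.approx(base.mean_error)
        assert shuffled.sd_error == pytest.approx(base.sd_error)

    def test_monte_carlo_reproducible_under_seed(self):
        rng = np.random.default_rng(23)
        labels = np.repeat([0.0, 40, 60, 80], 6)
        phi = labels / 8.0 + rng.normal(0, 0.3, labels.size)
        a = loocv_training_error(phi, labels, mode="monte-carlo", iterations=500, seed=4)
        b = loocv_training_error(phi, labels, mode="monte-carlo", iterations=500, seed=4)
        assert (a.mean_error, a.sd_error) == (b.mean_error, b.sd_error)
        c = loocv_training_error(phi, labels, mode="monte-carlo", iterations=500, seed=5)
        assert a.mean_error != c.mean_error

    def test_singleton_class_holdout_is_skipped(self):
        # class 80 has one window; holding it out collapses the class
        labels = np.array([0.0, 0, 40, 40, 80])
        phi = np.array([1.0, 1.2, 3.0, 3.2, 5.0])
        res = loocv_training_error(phi, labels)
        assert res.n_skipped == 1
        assert res.n_evaluated == 4


class TestModelFile:
    def test_json_round_trip(self, tmp_path):
        labels = np.repeat([0.0, 40, 60, 80], 4)
        phi = labels / 9.0 + 1.0
        est = RigidityCalibration(class_set=(0, 40, 60, 80)).fit(phi, labels)
        err = loocv_training_error(phi, labels, class_set=(0, 40, 60, 80))
        mf = RigidityModelFile.from_estimator(
            est, "phi_R", window_size=200, sampling_rate_hz=50.0, training_error=err
        )
        path = tmp_path / "model.json"
        mf.to_file(path)
        back = RigidityModelFile.from_file(path)
        assert back == mf
        probe = np.linspace(0, 10, 7)
        assert np.allclose(back.to_estimator().predict(probe), est.predict(probe))

    def test_unknown_descriptor_rejected(self):
        with pytest.raises(ValueError):
            RigidityModelFile(
                descriptor="phi_bogus",
                coefficients=(0, 1, 0),
                class_set=(0, 40),
                window_size=200,
                sampling_rate_hz=50.0,
            )
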