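"""Dense-net LVDdI regression, MAPE/accuracy, Bland-Altman, thresholding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from lvepulse.classify import split_dataset
from lvepulse.evaluate import roc_auc
from lvepulse.regress import (
    DenseNetConfig, DenseNetRegressor, train_regressor, predict_lvddi,
    mape_accuracy, bland_altman, regression_as_classifier)


def quick_config(**kwargs):
    defaults = dict(seed=0, epochs=40)
    defaults.update(kwargs)
    return DenseNetConfig(**defaults)


class TestDenseNetTraining:
    def test_constant_targets_learned(self, rng):
        X = rng.normal(size=(60, 5))
        y = np.full(60, 30.0)
        model, _ = train_regressor(X, y, quick_config())
        assert predict_lvddi(model, X) == pytest.approx(30.0, rel=0.05)

    def test_loss_drops_tenfold_on_powers_to_lvddi_map(self, recovery_cohort):
        # noise-free linear map from harmonic powers to LVDdI
        X, lvddi, y = recovery_cohort
        X_tr, _, _, _ = split_dataset(X, y, 0.2, seed=5)
        _, history = train_regressor(
            X.loc[X_tr.index], lvddi.loc[X_tr.index], DenseNetConfig(seed=5))
        assert history["train_mse"].iloc[-1] < history["train_mse"].iloc[0] / 10
        assert len(history) == 100

    def test_smoothed_loss_nonincreasing(self, recovery_cohort):
        X, lvddi, y = recovery_cohort
        X_tr, _, _, _ = split_dataset(X, y, 0.2, seed=5)
        _, history = train_regressor(
            X.loc[X_tr.index], lvddi.loc[X_tr.index], DenseNetConfig(seed=5))
        smoothed = history["train_mse"].rolling(10).mean().dropna().to_numpy()
        # non-increasing trend, tolerating small plateau oscillation (<=5%)
        assert np.all(np.diff(smoothed) <= 0.05 * smoothed[:-1])

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError):
            train_regressor(rng.normal(size=(5, 3)), np.ones(5), quick_config())

    def test_divergence_aborts_with_diagnostic(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        bad = quick_config(learning_rate=np.nan)
        with pytest.raises(RuntimeError, match="non-finite"):
            train_regressor(X, y, bad)


class TestDenseConnectivity:
    @pytest.mark.parametrize("d", [3, 100])
    def test_ablation_changes_parameter_count_by_concat_arithmetic(self, d):
        h1, h2 = 128, 32
        dense = DenseNetRegressor(d, quick_config(dense_connectivity=True))
        plain = DenseNetRegressor(d, quick_config(dense_connectivity=False))
        # dense block n consumes the concatenation of the input and all
        # previous outputs; the extra parameters are the widened batch-norm
        # (2 per extra input) and affine rows (out-width per extra input)
        extra_l2 = 2 * d + d * h2                  # layer 2 gains the raw input
        extra_l3 = 2 * (d + h1) + (d + h1) * 1     # output gains input + h1
        assert dense.n_parameters - plain.n_parameters == extra_l2 + extra_l3

    def test_both_variants_train(self, rng):
        X = rng.normal(size=(40, 6))
        y = 30 + X[:, 0] * 2
        for flag in (True, False):
            model, hist = train_regressor(
                X, y, quick_config(dense_connectivity=flag))
            assert np.isfinite(hist["train_mse"]).all()


class TestPredictLvddi:
    def test_same_input_same_output(self, rng):
        X = rng.normal(size=(30, 4))
        y = 30 + X[:, 0]
        model, _ = train_regressor(X, y, quick_config())
        assert np.array_equal(predict_lvddi(model, X), predict_lvddi(model, X))

    def test_batch_equals_per_item(self, rng):
        X = rng.normal(size=(30, 4))
        model, _ = train_regressor(X, 30 + X[:, 0], quick_config())
        batch = predict_lvddi(model, X[:5])
        single = np.concatenate([predict_lvddi(model, X[i]) for i in range(5)])
        assert batch == pytest.approx(single, abs=1e-12)

    def test_predictions_clamped_positive(self, rng):
        X = rng.normal(size=(30, 3))
        y = np.full(30, 0.2)  # near-zero target; floor keeps output positive
        model, _ = train_regressor(X, y, quick_config())
        assert (predict_lvddi(model, rng.normal(size=(10, 3)) * 10) > 0).all()

    def test_wrong_input_length_rejected(self, rng):
        X = rng.normal(size=(30, 4))
        model, _ = train_regressor(X, 30 + X[:, 0], quick_config())
        with pytest.raises(ValueError):
            predict_lvddi(model, rng.normal(size=(5, 7)))

    def test_parameter_recovery_held_out(self, recovery_cohort):
        """LVDdI is a known function of the harmonic powers; the net must
        recover it from held-out waveform features to within 10% MAPE."""
        X, lvddi, y = recovery_cohort
        X_tr, X_te, _, _ = split_dataset(X, y, 0.2, seed=5)
        model, _ = train_regressor(
            X.loc[X_tr.index], lvddi.loc[X_tr.index], DenseNetConfig(seed=5))
        pred = predict_lvddi(model, X.loc[X_te.index])
        mape, acc = mape_accuracy(lvddi.loc[X_te.index], pred)
        assert mape <= 10.0
        assert acc >= 0.90


class TestMapeAccuracy:
    def test_exact_prediction(self):
        mape, acc = mape_accuracy([10, 20, 30], [10, 20, 30])
        assert mape == 0.0 and acc == 1.0

    def test_hand_arithmetic(self):
        mape, acc = mape_accuracy([10, 20], [11, 18])
        assert mape == pytest.approx(10.0)
        assert acc == pytest.approx(0.90)

    def test_uniform_overprediction(self):
        mape, acc = mape_accuracy([10, 50, 90], [11.2, 56, 100.8])
        assert acc == pytest.approx(0.88)

    def test_zero_measured_rejected(self):
        with pytest.raises(ValueError):
            mape_accuracy([0, 10], [1, 10])

    @given(c=st.floats(0.01, 100))
    def test_scale_invariance(self, c):
        y = np.array([10.0, 25.0, 40.0])
        y_hat = np.array([12.0, 22.0, 41.0])
        base, _ = mape_accuracy(y, y_hat)
        scaled, _ = mape_accuracy(c * y, c * y_hat)
        assert scaled == pytest.approx(base, rel=1e-9)


class TestBlandAltman:
    def test_identical_series(self):
        ba = bland_altman([30, 40, 50], [30, 40, 50])
        assert ba.mean_difference == 0.0
        assert ba.lower_limit == ba.upper_limit == 0.0

    def test_constant_bias(self):
        ba = bland_altman([30, 40, 50], [32, 42, 52])
        assert ba.mean_difference == pytest.approx(2.0)
        assert ba.sd_difference == pytest.approx(0.0)

    def test_limits_symmetric_about_mean(self, rng):
        y = rng.normal(40, 5, 50)
        ba = bland_altman(y, y + rng.normal(0, 2, 50))
        mid = (ba.lower_limit + ba.upper_limit) / 2
        assert mid == pytest.approx(ba.mean_difference, abs=1e-12)

    def test_gaussian_coverage_large_n(self, rng):
        y = rng.normal(40, 5, 10_000)
        ba = bland_altman(y, y + rng.normal(0, 2, 10_000))
        assert ba.fraction_within_limits == pytest.approx(0.95, abs=0.01)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([30], [31])


class TestRegressionAsClassifier:
    def test_threshold_labels(self):
        preds = regression_as_classifier(
            [40.0, 36.0, 38.0, 36.5], ["male", "male", "female", "female"])
        assert list(preds.y_pred) == ["lve", "non_lve", "lve", "non_lve"]

    def test_exact_threshold_is_non_lve(self):
        preds = regression_as_classifier([36.0, 37.0], ["male", "female"])
        assert list(preds.y_pred) == ["non_lve", "non_lve"]

    def test_all_equal_predictions_auc_half(self):
        preds = regression_as_classifier(
            [38.0] * 6, ["male"] * 6,
            y_true=["lve", "lve", "lve", "non_lve", "non_lve", "non_lve"])
        assert roc_auc(preds).auc == pytest.approx(0.5)

    def test_score_monotone_in_margin_across_sexes(self):
        preds = regression_as_classifier([39.0, 39.0], ["male", "female"])
        # same prediction, higher margin for the male subject (threshold 36)
        assert preds.scores[0] > preds.scores[1]

    def test_nonfinite_prediction_rejected(self):
        with pytest.raises(ValueError):
            regression_as_classifier([np.nan], ["male"])
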