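"""Weighted-forest classification and baselines: splits, CV, weighting."""

import numpy as np
import pandas as pd
import pytest

from lvepulse.classify import (
    ClassifierConfig, split_dataset, train_weighted_forest, train_baseline,
    train_classifier, cross_validate, predict)
from lvepulse.evaluate import confusion, classification_metrics, roc_auc


class TestClassifierConfig:
    @pytest.mark.parametrize("kwargs", [
        {"class_weights": {"non_lve": 0, "lve": 4}},
        {"test_fraction": 1.0},
        {"cv_folds": 1},
        {"model_kind": "boost"},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ClassifierConfig(seed=0, **kwargs)


class TestSplitDataset:
    def test_fixture_sized_split_gives_paper_support(self, rng):
        X = pd.DataFrame(rng.normal(size=(227, 5)),
                         index=[f"S{i}" for i in range(227)])
        y = pd.Series(["lve"] * 90 + ["non_lve"] * 137, index=X.index)
        _, X_te, _, y_te = split_dataset(X, y, 0.2, seed=0)
        assert len(X_te) in (45, 46)

    def test_same_seed_identical_split(self, imbalanced_cohort):
        _, X, y = imbalanced_cohort
        a = split_dataset(X, y, 0.2, seed=3)
        b = split_dataset(X, y, 0.2, seed=3)
        assert list(a[1].index) == list(b[1].index)

    def test_stratified_small_case(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 3)))
        y = pd.Series(["lve"] * 5 + ["non_lve"] * 5, index=X.index)
        _, X_te, _, y_te = split_dataset(X, y, 0.2, seed=0)
        assert len(X_te) == 2
        assert set(y_te) == {"lve", "non_lve"}

    def test_disjoint_and_covering(self, imbalanced_cohort):
        _, X, y = imbalanced_cohort
        X_tr, X_te, _, _ = split_dataset(X, y, 0.2, seed=1)
        assert set(X_tr.index).isdisjoint(X_te.index)
        assert set(X_tr.index) | set(X_te.index) == set(X.index)

    def test_single_class_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 3)))
        y = pd.Series(["lve"] * 10, index=X.index)
        with pytest.raises(ValueError):
            split_dataset(X, y, 0.2, seed=0)


class TestWeightedForest:
    def test_separable_training_accuracy_one(self, separable_cohort):
        _, X, y = separable_cohort
        config = ClassifierConfig(seed=1)
        model = train_weighted_forest(X, y, config)
        preds = predict(model, X, y_true=y)
        assert classification_metrics(confusion(preds))["accuracy"] == 1.0

    def test_minority_recall_nondecreasing_with_weight(self, imbalanced_cohort):
        _, X, y = imbalanced_cohort
        X_tr, X_te, y_tr, y_te = split_dataset(X, y, 0.2, seed=2)
        recalls = {}
        for w in (1.0, 4.0):
            config = ClassifierConfig(
                seed=2, class_weights={"non_lve": 1.0, "lve": w})
            model = train_weighted_forest(X_tr, y_tr, config)
            preds = predict(model, X_te, y_true=y_te)
            recalls[w] = classification_metrics(confusion(preds))["recall"]
        assert recalls[4.0] >= recalls[1.0]

    def test_single_class_training_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 3)))
        y = pd.Series(["lve"] * 10, index=X.index)
        with pytest.raises(ValueError):
            train_weighted_forest(X, y, ClassifierConfig(seed=0))

    def test_deterministic_given_seed(self, imbalanced_cohort):
        _, X, y = imbalanced_cohort
        config = ClassifierConfig(seed=5)
        p1 = predict(train_weighted_forest(X, y, config), X)
        p2 = predict(train_weighted_forest(X, y, config), X)
        assert np.array_equal(p1.scores, p2.scores)


class TestBaselines:
    @pytest.mark.parametrize("kind", ["svm", "fcnn"])
    def test_separable_training_accuracy_one(self, separable_cohort, kind):
        _, X, y = separable_cohort
        model = train_baseline(X, y, ClassifierConfig(seed=1), model_kind=kind)
        preds = predict(model, X, y_true=y)
        assert classification_metrics(confusion(preds))["accuracy"] == 1.0

    @pytest.mark.parametrize("kind", ["svm", "fcnn"])
    def test_deterministic_given_seed(self, separable_cohort, kind):
        _, X, y = separable_cohort
        cfg = ClassifierConfig(seed=4, model_kind=kind)
        p1 = predict(train_baseline(X, y, cfg), X)
        p2 = predict(train_baseline(X, y, cfg), X)
        assert np.array_equal(p1.scores, p2.scores)

    def test_wrf_not_a_baseline(self, separable_cohort):
        _, X, y = separable_cohort
        with pytest.raises(ValueError):
            train_baseline(X, y, ClassifierConfig(seed=0), model_kind="wrf")


class TestPredict:
    def test_training_set_prediction_separable_all_correct(self, separable_cohort):
        _, X, y = separable_cohort
        model = train_classifier(X, y, ClassifierConfig(seed=1))
        preds = predict(model, X, y_true=y)
        assert (preds.y_pred == np.asarray(y)).all()

    def test_empty_test_set(self, separable_cohort):
        _, X, y = separable_cohort
        model = train_classifier(X, y, ClassifierConfig(seed=1))
        preds = predict(model, X.iloc[:0])
        assert len(preds) == 0

    def test_feature_length_mismatch_rejected(self, separable_cohort):
        _, X, y = separable_cohort
        model = train_classifier(X, y, ClassifierConfig(seed=1))
        with pytest.raises(ValueError):
            predict(model, X.iloc[:, :10])

    def test_monotone_score_map_preserves_auc(self, imbalanced_cohort):
        _, X, y = imbalanced_cohort
        X_tr, X_te, y_tr, y_te = split_dataset(X, y, 0.3, seed=1)
        model = train_classifier(X_tr, y_tr, ClassifierConfig(seed=1))
        preds = predict(model, X_te, y_true=y_te)
        auc0 = roc_auc(preds).auc
        import dataclasses
        warped = dataclasses.replace(
            preds, scores=np.exp(3.0 * preds.scores))
        assert roc_auc(warped).auc == pytest.approx(auc0, abs=1e-12)


class TestCrossValidate:
    def test_perfect_separability_mean_accuracy_one(self):
        # harmonic-power features put the two regimes far apart in 3-D
        from conftest import cohort_features
        import lvepulse as lp
        config = lp.GeneratorConfig(
            n_non_lve=60, n_lve=20,
            harmonic_power_means={"non_lve": (3.5, 0.4, 0.1),
                                  "lve": (1.5, 1.4, 0.4)},
            harmonic_power_sds={"non_lve": (0.1, 0.05, 0.02),
                                "lve": (0.1, 0.05, 0.02)},
            noise_sd=0.05, seed=21)
        _, X, y = cohort_features(config, mode="powers")
        cv = cross_validate(X, y, ClassifierConfig(seed=1))
        assert cv["mean_accuracy"] == 1.0

    def test_folds_partition_cohort(self, imbalanced_cohort):
        _, X, y = imbalanced_cohort
        cv = cross_validate(X, y, ClassifierConfig(seed=2))
        all_idx = np.concatenate([f["test_indices"] for f in cv["folds"]])
        assert sorted(all_idx) == list(range(len(X)))

    def test_mean_is_unweighted_fold_mean(self, imbalanced_cohort):
        _, X, y = imbalanced_cohort
        cv = cross_validate(X, y, ClassifierConfig(seed=2))
        assert cv["mean_accuracy"] == pytest.approx(
            np.mean([f["accuracy"] for f in cv["folds"]]))

    def test_too_many_folds_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(12, 3)))
        y = pd.Series(["lve"] * 3 + ["non_lve"] * 9, index=X.index)
        with pytest.raises(ValueError):
            cross_validate(X, y, ClassifierConfig(seed=0, cv_folds=5))

    def test_permuted_labels_accuracy_near_prevalence(self, imbalanced_cohort):
        _, X, y = imbalanced_cohort
        rng = np.random.default_rng(123)
        accs = []
        for i in range(3):
            y_perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
            cv = cross_validate(
                X, y_perm,
                ClassifierConfig(seed=i,
                                 class_weights={"non_lve": 1.0, "lve": 1.0}))
            accs.append(cv["mean_accuracy"])
        prevalence = (y == "non_lve").mean()
        assert np.mean(accs) == pytest.approx(prevalence, abs=0.1)
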