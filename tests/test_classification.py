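"""Weighted SVM, Platt scaling, nested LOOCV, ROC statistics."""

import numpy as np
import pytest

from dkitex import (
    anova_filtered_loocv,
    compare_auc_paired,
    generate_tabular_features,
    group_tests,
    nested_loocv,
    platt_calibrate,
    roc_auc,
    train_weighted_svm,
)
from dkitex.classification import (
    SMALL_C_GRID,
    SMALL_GAMMA_GRID,
    SvmConfig,
    balanced_class_weights,
    standardize_train_test,
)


class TestWeightedSvm:
    def test_separable_toy_set_training_accuracy(self):
        X = np.array([[0.0, 0], [0, 1], [1, 0], [3, 3], [4, 3], [3, 4]])
        y = np.array([0, 0, 0, 1, 1, 1])
        clf = train_weighted_svm(X, y, c=1000.0, gamma=0.5)
        assert np.array_equal(clf.predict(X), y)

    def test_duplicating_minority_equals_doubling_weight(self, rng):
        X = rng.normal(size=(12, 3))
        y = np.array([0] * 8 + [1] * 4)
        X[y == 1] += 1.0
        X_dup = np.vstack([X, X[y == 1]])
        y_dup = np.concatenate([y, np.ones(4, dtype=int)])
        probe = rng.normal(size=(5, 3))
        a = train_weighted_svm(X_dup, y_dup, 2.0, 0.3, None).decision_function(probe)
        b = train_weighted_svm(X, y, 2.0, 0.3, {0: 1.0, 1: 2.0}).decision_function(probe)
        assert np.allclose(a, b, atol=1e-6)

    def test_constant_feature_is_inert_after_standardization(self, rng):
        X = rng.normal(size=(14, 4))
        y = np.array([0] * 7 + [1] * 7)
        X_aug = np.column_stack([X, np.full(14, 9.9)])
        Xs = standardize_train_test(X)
        Xs_aug = standardize_train_test(X_aug)
        probe = Xs[:5]
        probe_aug = Xs_aug[:5]
        a = train_weighted_svm(Xs, y, 4.0, 0.2).decision_function(probe)
        b = train_weighted_svm(Xs_aug, y, 4.0, 0.2).decision_function(probe_aug)
        assert np.allclose(a, b, atol=1e-10)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_weighted_svm(np.eye(3), np.zeros(3, dtype=int), 1.0, 0.1)

    def test_balanced_weights_formula(self):
        w = balanced_class_weights(np.array([0] * 26 + [1] * 11))
        assert w[0] == pytest.approx(37 / 52)
        assert w[1] == pytest.approx(37 / 22)


class TestPlattScaling:
    def test_monotone_and_label_ordered_when_separated(self, rng):
        f = np.concatenate([rng.normal(-3, 0.5, 15), rng.normal(3, 0.5, 15)])
        y = np.array([0] * 15 + [1] * 15)
        cal = platt_calibrate(f, y)
        assert cal.a < 0
        grid = np.linspace(-5, 5, 50)
        assert np.all(np.diff(cal(grid)) > 0)
        assert cal(3.0) > 0.9 and cal(-3.0) < 0.1

    def test_symmetric_inputs_give_half_probability_at_zero(self, rng):
        d = np.concatenate([-np.linspace(0.5, 2, 20), np.linspace(0.5, 2, 20)])
        y = np.array([0] * 20 + [1] * 20)
        cal = platt_calibrate(d, y)
        assert cal(0.0) == pytest.approx(0.5, abs=1e-3)

    def test_uninformative_scores_approach_class_prior(self, rng):
        f = rng.normal(size=300)
        y = (rng.random(300) < 0.3).astype(int)
        cal = platt_calibrate(f, y)
        prior = y.mean()
        probs = cal(np.linspace(-2, 2, 9))
        assert np.allclose(probs, prior, atol=0.1)

    def test_calibration_preserves_ranking_hence_auc(self, rng):
        f = rng.normal(size=100)
        y = (rng.random(100) < 1 / (1 + np.exp(-f))).astype(int)
        cal = platt_calibrate(f, y)
        assert roc_auc(cal(f), y).auc == pytest.approx(roc_auc(f, y).auc, abs=1e-12)

    def test_degenerate_values_rejected(self):
        with pytest.raises(ValueError):
            platt_calibrate(np.ones(10), np.array([0, 1] * 5))


class TestRocAuc:
    def test_perfect_scores(self):
        y = np.array([0, 1, 0, 1, 1])
        r = roc_auc(y.astype(float), y)
        assert r.auc == 1.0 and r.sensitivity == 1.0 and r.specificity == 1.0

    def test_pairwise_counting_example(self):
        r = roc_auc([0.9, 0.8, 0.7, 0.6], [1, 1, 0, 1])
        assert r.auc == pytest.approx(2 / 3)

    def test_random_scores_near_half(self, rng):
        y = (rng.random(1000) < 0.5).astype(int)
        r = roc_auc(rng.random(1000), y)
        assert r.auc == pytest.approx(0.5, abs=0.05)

    def test_confusion_consistency(self, rng):
        p = rng.random(60)
        y = (rng.random(60) < 0.4).astype(int)
        r = roc_auc(p, y)
        tn, fp, fn, tp = r.confusion.ravel()
        assert tp + tn + fp + fn == 60
        assert r.accuracy == pytest.approx((tp + tn) / 60)


class TestDeLong:
    def test_identical_curves(self, rng):
        s = rng.random(40)
        y = (rng.random(40) < 0.5).astype(int)
        cmp = compare_auc_paired(s, s, y)
        assert cmp.delta == 0.0 and cmp.p_value == 1.0

    def test_power_informative_vs_noise(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            y = np.array([0] * 100 + [1] * 100)
            informative = y + rng.normal(0, 0.7, 200)
            noise = rng.normal(size=200)
            if compare_auc_paired(informative, noise, y).p_value < 0.05:
                hits += 1
        assert hits >= 45  # >= 90% of 50 seeds

    def test_variance_close_to_bootstrap(self):
        rng = np.random.default_rng(0)
        y = np.array([0] * 100 + [1] * 100)
        a = y + rng.normal(0, 1.2, 200)
        b = y + rng.normal(0, 1.8, 200)
        cmp = compare_auc_paired(a, b, y)
        deltas = []
        for _ in range(600):
            idx = rng.integers(0, 200, 200)
            while len(np.unique(y[idx])) < 2:
                idx = rng.integers(0, 200, 200)
            deltas.append(
                roc_auc(a[idx], y[idx]).auc - roc_auc(b[idx], y[idx]).auc
            )
        boot_var = np.var(deltas)
        delong_var = (cmp.delta / cmp.z) ** 2
        assert delong_var == pytest.approx(boot_var, rel=0.15)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_auc_paired([0.1, 0.2], [0.3], [0, 1])


class TestGroupTests:
    def test_identical_groups_non_significant(self):
        g = np.arange(10.0)
        out = group_tests([g, g.copy()])
        assert out["anova_p"] > 0.9

    def test_anova_power_two_shifted_normals(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            out = group_tests([rng.normal(0, 1, 50), rng.normal(1, 1, 50)])
            hits += out["anova_p"] < 0.05
        assert hits >= 95

    def test_kruskal_rank_invariance(self, rng):
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1, 30)
        p1 = group_tests([a, b])["kruskal_p"]
        p2 = group_tests([np.exp(a), np.exp(b)])["kruskal_p"]
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_chi2_on_contingency(self):
        out = group_tests([np.arange(5.0), np.arange(5.0) + 1], contingency=[[20, 5], [6, 18]])
        assert out["chi2_p"] < 0.01


class TestNestedLoocv:
    def test_fold_count_equals_subjects(self, small_svm_config):
        X, y = generate_tabular_features(16, 6, informative_idx=[1], effect_size=2.0, class_ratio=(9, 7), seed=0)
        run = nested_loocv(X, y, small_svm_config)
        assert run.n_folds == 16
        assert len(run.params) == 16

    def test_deterministic_given_config(self, small_svm_config):
        X, y = generate_tabular_features(14, 6, informative_idx=[1, 2], effect_size=2.0, class_ratio=(8, 6), seed=1)
        a = nested_loocv(X, y, small_svm_config)
        b = nested_loocv(X, y, small_svm_config)
        assert np.array_equal(a.probabilities, b.probabilities)
        assert a.params == b.params

    def test_held_out_subject_cannot_influence_its_own_fold(self, small_svm_config):
        """Replacing the held-out subject's features must not change that
        fold's hyperparameter choice (training never sees the subject)."""
        X, y = generate_tabular_features(14, 6, informative_idx=[1], effect_size=2.0, class_ratio=(8, 6), seed=2)
        i = 5
        X2 = X.copy()
        X2[i] = 1e3  # absurd feature values for the held-out subject
        a = nested_loocv(X, y, small_svm_config)
        b = nested_loocv(X2, y, small_svm_config)
        assert a.params[i] == b.params[i]

    def test_metrics_consistent_with_confusion(self, small_svm_config):
        X, y = generate_tabular_features(14, 6, informative_idx=[1], effect_size=2.5, class_ratio=(8, 6), seed=3)
        run = nested_loocv(X, y, small_svm_config)
        tn, fp, fn, tp = run.confusion.ravel()
        assert run.accuracy == pytest.approx((tp + tn) / 14)
        assert run.sensitivity == pytest.approx(tp / (tp + fn))
        assert run.specificity == pytest.approx(tn / (tn + fp))

    def test_feature_subset_restricts_columns(self, small_svm_config):
        X, y = generate_tabular_features(14, 8, informative_idx=[1], effect_size=3.0, class_ratio=(7, 7), seed=4)
        run_good = nested_loocv(X, y, small_svm_config, feature_subset=[0])
        run_noise = nested_loocv(X, y, small_svm_config, feature_subset=[5, 6])
        assert run_good.auc > run_noise.auc

    def test_too_small_cohort_rejected(self, small_svm_config):
        with pytest.raises(ValueError):
            nested_loocv(np.eye(3), np.array([0, 1, 0]), small_svm_config)


class TestAnovaFilteredLoocv:
    def _location_shift_cohort(self, seed=0, n=24):
        """mean/median/p5/p95 carry the class shift; SD/kurtosis pure noise."""
        rng = np.random.default_rng(seed)
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        X = rng.normal(size=(n, 6))
        for col in (0, 1, 4, 5):  # mean, median, p5, p95
            X[y == 1, col] += 2.5
        return X, y

    def test_consistently_selected_location_statistics(self, small_svm_config):
        X, y = self._location_shift_cohort()
        run, per_fold, consistent = anova_filtered_loocv(X, y, small_svm_config)
        assert consistent == {"mean", "median", "p5", "p95"}
        assert run.accuracy > 0.8

    def test_constant_feature_never_selected(self, small_svm_config):
        X, y = self._location_shift_cohort(seed=1)
        X[:, 3] = 7.0  # kurtosis column identical across classes
        _, per_fold, _ = anova_filtered_loocv(X, y, small_svm_config)
        assert all("kurtosis" not in sel for sel in per_fold)

    def test_pure_noise_falls_back_to_best_single_feature(self, small_svm_config):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 6))
        y = np.array([0, 1] * 6)
        run, per_fold, _ = anova_filtered_loocv(X, y, small_svm_config)
        assert all(len(sel) >= 1 for sel in per_fold)
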