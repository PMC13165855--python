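"""Split protocols, metrics arithmetic, fold statistics."""

import numpy as np
import pytest

from dcamnet.evaluation import (
    ConfusionMatrix,
    aggregate_folds,
    balanced_subject_subset,
    confusion_metrics,
    make_loso_folds,
    make_subject_mixed_split,
    paired_fold_tests,
    resample_stability,
)


def _balanced(n=800, n_subjects=8):
    y = np.tile([0, 1], n // 2)
    subjects = np.repeat([f"S{i}" for i in range(n_subjects)], n // n_subjects)
    return y, subjects


class TestSubjectMixedSplit:
    @pytest.mark.parametrize(
        "fraction,n_train,n_test", [(0.7, 560, 240), (0.8, 640, 160)]
    )
    def test_split_sizes(self, fraction, n_train, n_test):
        y, subjects = _balanced()
        plan = make_subject_mixed_split(y, subjects, train_fraction=fraction, seed=0)
        fold = plan.folds[0]
        assert len(fold.train_idx) + len(fold.val_idx) == n_train
        assert len(fold.test_idx) == n_test

    def test_stratification_within_one_sample(self):
        y, subjects = _balanced()
        fold = make_subject_mixed_split(y, subjects, seed=3).folds[0]
        for idx in (np.concatenate([fold.train_idx, fold.val_idx]), fold.test_idx):
            assert abs(np.mean(y[idx]) - 0.5) <= 1.0 / len(idx)

    def test_deterministic_under_seed(self):
        y, subjects = _balanced()
        a = make_subject_mixed_split(y, subjects, seed=9).folds[0]
        b = make_subject_mixed_split(y, subjects, seed=9).folds[0]
        np.testing.assert_array_equal(a.train_idx, b.train_idx)
        np.testing.assert_array_equal(a.test_idx, b.test_idx)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            make_subject_mixed_split(np.zeros(10), None)


class TestLosoFolds:
    @pytest.mark.parametrize("n_subjects", [2, 11, 21])
    def test_one_fold_per_subject(self, n_subjects):
        subjects = np.repeat([f"S{i}" for i in range(n_subjects)], 10)
        y = np.tile([0, 1], len(subjects) // 2)
        plan = make_loso_folds(subjects, y, seed=0)
        assert len(plan.folds) == n_subjects

    def test_coverage_and_disjointness(self):
        subjects = np.repeat(["A", "B", "C", "D"], 12)
        y = np.tile([0, 1], 24)
        plan = make_loso_folds(subjects, y, seed=1)
        tested = np.concatenate([f.test_idx for f in plan.folds])
        assert sorted(tested) == list(range(len(subjects)))  # each sample tested once
        for f in plan.folds:
            train_subjects = set(subjects[np.concatenate([f.train_idx, f.val_idx])])
            assert f.held_out not in train_subjects

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            make_loso_folds(np.repeat("A", 10))


class TestConfusionMetrics:
    def test_loso_aggregate_sensitivity_specificity(self):
        report = confusion_metrics(ConfusionMatrix(tp=890, fn=160, fp=150, tn=900))
        assert report.sensitivity == pytest.approx(84.8, abs=0.05)
        assert report.specificity == pytest.approx(85.7, abs=0.05)

    def test_error_rate_from_error_counts(self):
        # 7 false alarms + 1 miss on a 240-sample balanced test set
        report = confusion_metrics(ConfusionMatrix(tp=119, fn=1, fp=7, tn=113))
        assert report.error_rate == pytest.approx(3.33, abs=0.005)

    def test_perfect_predictions(self):
        report = confusion_metrics(ConfusionMatrix(tp=10, fn=0, fp=0, tn=10))
        assert report.accuracy == report.precision == report.recall == report.f1 == 100.0

    def test_f1_is_harmonic_mean(self):
        r = confusion_metrics(ConfusionMatrix(tp=30, fn=10, fp=20, tn=40))
        assert r.f1 == pytest.approx(2 * r.precision * r.recall / (r.precision + r.recall))

    def test_zero_denominator_flagged_not_zeroed(self):
        r = confusion_metrics(ConfusionMatrix(tp=0, fn=0, fp=0, tn=5))
        assert "precision" in r.undefined and np.isnan(r.precision)

    def test_from_predictions(self):
        cm = ConfusionMatrix.from_predictions([1, 1, 0, 0], [1, 0, 1, 0])
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (1, 1, 1, 1)


class TestFoldAggregation:
    def test_two_fold_mean_and_sum(self):
        m1 = ConfusionMatrix(8, 2, 0, 10)  # 90%
        m2 = ConfusionMatrix(6, 4, 0, 10)  # 80%
        res = aggregate_folds([m1, m2])
        assert res.mean == pytest.approx(85.0)
        assert res.aggregate == ConfusionMatrix(14, 6, 0, 20)

    def test_identical_folds_zero_sd(self):
        m = ConfusionMatrix(9, 1, 1, 9)
        res = aggregate_folds([m, m, m])
        assert res.sd == 0.0

    def test_hand_computed_mean_sd_ci(self):
        mats = [ConfusionMatrix(tp=k, fn=10 - k, fp=0, tn=10) for k in (6, 7, 8, 9)]
        res = aggregate_folds(mats)
        accs = np.array([80.0, 85.0, 90.0, 95.0])
        assert res.mean == pytest.approx(accs.mean(), abs=1e-9)
        assert res.sd == pytest.approx(accs.std(ddof=1), abs=1e-9)
        half = 1.96 * accs.std(ddof=1) / 2.0
        assert res.ci95 == pytest.approx((accs.mean() - half, accs.mean() + half))

    def test_aggregate_accuracy_is_sample_weighted_fold_mean(self):
        mats = [ConfusionMatrix(5, 0, 1, 4), ConfusionMatrix(10, 5, 0, 15)]
        res = aggregate_folds(mats)
        weighted = sum(
            confusion_metrics(m).accuracy * m.total for m in mats
        ) / sum(m.total for m in mats)
        assert confusion_metrics(res.aggregate).accuracy == pytest.approx(weighted)


class TestPairedFoldTests:
    def test_closed_form_paired_t(self):
        b = np.array([80.0, 81.0, 79.0, 82.0, 80.5])
        a = b + np.array([1.0, 2.0, 3.0, 2.0, 1.0])
        res = paired_fold_tests(a, b)
        d_mean, d_sd = 1.8, 0.8366600265
        assert res.cohens_d == pytest.approx(d_mean / d_sd, abs=1e-6)
        assert res.t_stat == pytest.approx(d_mean / (d_sd / np.sqrt(5)), abs=1e-6)

    def test_equal_vectors_degenerate(self):
        a = np.array([80.0, 81.0, 82.0, 83.0, 84.0])
        res = paired_fold_tests(a, a)
        assert res.flags and np.isnan(res.cohens_d)

    def test_constant_shift_flagged(self):
        b = np.array([80.0, 81.0, 82.0, 83.0, 84.0])
        res = paired_fold_tests(b + 1.0, b)
        assert any("undefined" in f for f in res.flags)
        assert np.isnan(res.cohens_d)

    def test_all_positive_differences_maximal_w(self):
        b = np.linspace(70, 90, 21)
        a = b + np.linspace(1, 3, 21)
        res = paired_fold_tests(a, b)
        assert res.wilcoxon_w == 21 * 22 / 2
        assert res.wilcoxon_p < 1e-4


class TestBalancedSubsets:
    def test_equal_per_subject_quota(self):
        y, subjects = _balanced(n=160, n_subjects=4)
        sel = balanced_subject_subset(y, subjects, per_class=40, seed=0)
        assert len(sel) == 80
        assert np.mean(y[sel]) == 0.5
        counts = {s: np.sum(subjects[sel] == s) for s in np.unique(subjects)}
        assert all(c == 20 for c in counts.values())

    def test_deterministic_under_seed(self):
        y, subjects = _balanced(n=160, n_subjects=4)
        a = balanced_subject_subset(y, subjects, 30, seed=100)
        b = balanced_subject_subset(y, subjects, 30, seed=100)
        np.testing.assert_array_equal(a, b)

    def test_scales_down_with_warning(self):
        y, subjects = _balanced(n=40, n_subjects=4)
        with pytest.warns(UserWarning, match="scaling"):
            sel = balanced_subject_subset(y, subjects, per_class=100, seed=0)
        assert len(sel) == 40


class TestResampleStability:
    def test_majority_stub_is_flat_across_seeds(self):
        y, subjects = _balanced(n=200, n_subjects=4)
        X = np.zeros((200, 1))
        out = resample_stability(
            X, y, subjects,
            fit_eval=lambda Xtr, ytr, Xte, yte, seed: 100.0 * np.mean(yte == 1),
            per_class=40, seeds=(100, 200, 300),
        )
        assert out["sd"] == pytest.approx(0.0, abs=1e-9)
        assert out["mean"] == pytest.approx(50.0, abs=2.0)
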