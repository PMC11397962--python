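import numpy as np
import pytest

from emgphasor.evaluate import (
    DiagonalLda,
    EvalConfig,
    accuracy,
    loto_folds,
    mcc_multiclass,
    run_subject_eval,
    svm_gamma,
    zscore_fit_apply,
)
from emgphasor.features_classic import FeatureMatrix


def literal_rk(C):
    """Literal triple-sum transcription of the multiclass R_K formula."""
    K = C.shape[0]
    num = 0.0
    for k in range(K):
        for l in range(K):
            for m in range(K):
                num += C[k, k] * C[l, m] - C[k, l] * C[m, k]
    den1 = 0.0
    for k in range(K):
        row_k = sum(C[k, l] for l in range(K))
        rest = sum(C[kp, lp] for kp in range(K) if kp != k for lp in range(K))
        den1 += row_k * rest
    den2 = 0.0
    for k in range(K):
        col_k = sum(C[l, k] for l in range(K))
        rest = sum(C[lp, kp] for kp in range(K) if kp != k for lp in range(K))
        den2 += col_k * rest
    den = np.sqrt(den1) * np.sqrt(den2)
    return num / den if den else 0.0


def one_hot_features(labels, trial_ids, name="onehot"):
    k = int(labels.max()) + 1
    values = np.eye(k)[labels]
    return FeatureMatrix(
        values=values,
        feature_names=[f"c{i}" for i in range(k)],
        labels=labels,
        trial_ids=trial_ids,
        subject_id=0,
        name=name,
    )


class TestLotoFolds:
    def test_ten_trials_five_folds(self):
        trial_ids = np.repeat(np.arange(10), 7)
        folds = loto_folds(trial_ids, 5)
        assert len(folds) == 5
        all_test = np.concatenate([t for _, t in folds])
        assert all(len(t) == 2 for _, t in folds)
        np.testing.assert_array_equal(np.sort(all_test), np.arange(10))

    def test_five_trials_is_leave_one_out(self):
        folds = loto_folds(np.arange(5), 5)
        assert all(len(t) == 1 for _, t in folds)

    def test_disjoint_train_test(self):
        folds = loto_folds(np.arange(10), 5)
        for train, test in folds:
            assert not set(train) & set(test)
            assert set(train) | set(test) == set(range(10))

    def test_too_few_trials(self):
        with pytest.raises(ValueError):
            loto_folds(np.arange(3), 5)

    def test_shuffled_folds_deterministic(self):
        a = loto_folds(np.arange(10), 5, seed=1)
        b = loto_folds(np.arange(10), 5, seed=1)
        for (_, ta), (_, tb) in zip(a, b):
            np.testing.assert_array_equal(ta, tb)


class TestZscore:
    def test_constant_train_column_maps_to_zero(self, rng):
        train = np.column_stack([np.full(10, 3.0), rng.standard_normal(10)])
        test = np.column_stack([np.full(4, 99.0), rng.standard_normal(4)])
        zt, zs = zscore_fit_apply(train, test)
        assert np.all(zt[:, 0] == 0.0)
        assert np.all(zs[:, 0] == 0.0)

    def test_train_standardized(self, rng):
        train = rng.standard_normal((50, 4)) * 3.0 + 7.0
        zt, _ = zscore_fit_apply(train, train)
        np.testing.assert_allclose(zt.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(zt.std(axis=0), 1.0, atol=1e-9)

    def test_test_uses_train_statistics(self, rng):
        train = rng.standard_normal((100, 2))
        shift = 5.0
        _, zs = zscore_fit_apply(train, train + shift)
        expected = (train + shift - train.mean(axis=0)) / train.std(axis=0)
        np.testing.assert_allclose(zs, expected)

    def test_single_row_raises(self):
        with pytest.raises(ValueError):
            zscore_fit_apply(np.ones((1, 2)), np.ones((1, 2)))


class TestSvmGamma:
    def test_unit_variance_rules(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((4000, 72))
        x = (x - x.mean()) / x.std()
        assert svm_gamma(x, "paper_product") == pytest.approx(72.0, rel=1e-6)
        assert svm_gamma(x, "inverse_scale") == pytest.approx(1 / 72.0, rel=1e-6)

    def test_doubling_features_doubles_product_gamma(self, rng):
        x = rng.standard_normal((100, 10))
        g1 = svm_gamma(x, "paper_product") / (10 * x.var())
        xx = np.hstack([x, x])
        g2 = svm_gamma(xx, "paper_product") / (20 * xx.var())
        assert g1 == pytest.approx(g2)

    def test_flattened_variance_convention(self, rng):
        x = rng.standard_normal((200, 3)) * np.array([1.0, 5.0, 0.1])
        assert svm_gamma(x, "paper_product") == pytest.approx(3 * x.var())

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            svm_gamma(np.ones((10, 2)), "paper_product")


class TestMcc:
    def test_perfect_diagonal(self):
        assert mcc_multiclass(np.diag([5, 9, 2, 7])) == pytest.approx(1.0)

    def test_constant_predictor_is_zero(self):
        conf = np.zeros((3, 3))
        conf[:, 1] = [10, 20, 5]  # everything predicted as class 1
        with pytest.warns(RuntimeWarning):
            assert mcc_multiclass(conf) == 0.0

    def test_random_confusions_match_literal_formula(self, rng):
        for _ in range(100):
            conf = rng.integers(0, 30, (5, 5)).astype(float)
            if conf.sum() == 0:
                continue
            assert mcc_multiclass(conf) == pytest.approx(literal_rk(conf), abs=1e-12)

    def test_bounds(self, rng):
        for _ in range(20):
            conf = rng.integers(0, 50, (4, 4)).astype(float)
            if conf.sum() == 0:
                continue
            assert -1.0 <= mcc_multiclass(conf) <= 1.0


def test_accuracy_is_trace_over_sum(rng):
    conf = rng.integers(0, 40, (5, 5)).astype(float)
    assert accuracy(conf) == np.trace(conf) / conf.sum()


class TestDiagonalLda:
    def test_separable_means(self, rng):
        x = np.vstack([rng.standard_normal((200, 2)) + [0, 0],
                       rng.standard_normal((200, 2)) + [10, 10]])
        y = np.repeat([0, 1], 200)
        clf = DiagonalLda().fit(x, y)
        assert np.mean(clf.predict(x) == y) > 0.99

    def test_ignores_correlations(self, rng):
        # diagonal model: a feature with tiny variance dominates
        x = np.vstack([np.column_stack([rng.standard_normal(100) * 5, rng.standard_normal(100) * 0.01]),
                       np.column_stack([rng.standard_normal(100) * 5, rng.standard_normal(100) * 0.01 + 1.0])])
        y = np.repeat([0, 1], 100)
        clf = DiagonalLda().fit(x, y)
        assert np.mean(clf.predict(x) == y) > 0.95


class TestRunSubjectEval:
    def _trials(self, n_rows, n_trials=10, rng=None):
        return np.tile(np.arange(n_trials), n_rows // n_trials + 1)[:n_rows]

    @pytest.mark.parametrize("clf", ["lda_diag", "svm_rbf"])
    def test_one_hot_features_are_perfect(self, rng, clf):
        labels = rng.integers(0, 5, 600)
        fm = one_hot_features(labels, self._trials(600))
        res = run_subject_eval(fm, EvalConfig(classifier=clf))
        assert res.acc_mean == 1.0
        assert res.mcc_mean == pytest.approx(1.0)

    def test_shuffled_labels_give_null_mcc(self, rng):
        n = 2500
        values = rng.standard_normal((n, 8))
        labels = rng.integers(0, 5, n)  # independent of features
        fm = FeatureMatrix(values, [f"f{i}" for i in range(8)], labels,
                           self._trials(n), 0, "null")
        res = run_subject_eval(fm, EvalConfig(classifier="lda_diag"))
        assert abs(res.mcc_mean) < 0.1

    def test_confusion_consistency(self, rng):
        labels = rng.integers(0, 4, 800)
        values = np.eye(4)[labels] + 0.5 * rng.standard_normal((800, 4))
        fm = FeatureMatrix(values, [f"f{i}" for i in range(4)], labels,
                           self._trials(800), 0, "noisy")
        res = run_subject_eval(fm, EvalConfig(classifier="lda_diag"))
        # pooled confusion rows = per-class test counts; ACC = trace/sum
        assert res.confusion.sum() == 800
        np.testing.assert_array_equal(res.confusion.sum(axis=1), np.bincount(labels))
        pooled_acc = np.trace(res.confusion) / res.confusion.sum()
        assert 0.0 <= pooled_acc <= 1.0

    def test_missing_class_fold_skipped(self, rng):
        # class 4 lives only in trials 0-1 -> the fold testing those trials
        # has no class-4 training rows... construct the opposite: class 4
        # appears ONLY in trial 0, so the fold testing trial 0 trains without it
        n = 500
        labels = rng.integers(0, 4, n)
        trials = self._trials(n, n_trials=5)
        labels[trials == 0] = 4
        values = np.eye(5)[labels] + 0.1 * rng.standard_normal((n, 5))
        fm = FeatureMatrix(values, [f"f{i}" for i in range(5)], labels, trials, 0, "gap")
        res = run_subject_eval(fm, EvalConfig(classifier="lda_diag"))
        assert res.skipped_folds == [0]
        assert len(res.fold_acc) == 4

    def test_no_information_leak_from_test_labels(self, rng):
        # a trained model's predictions cannot depend on the held-out labels
        labels = rng.integers(0, 3, 600)
        values = np.eye(3)[labels] + 0.8 * rng.standard_normal((600, 3))
        trials = self._trials(600)
        train_mask = ~np.isin(trials, [0, 1])
        x_tr, x_te = zscore_fit_apply(values[train_mask], values[~train_mask])
        clf = DiagonalLda().fit(x_tr, labels[train_mask])
        preds_before = clf.predict(x_te)
        # shuffling the test labels touches nothing the model saw
        _ = rng.permutation(labels[~train_mask])
        preds_after = clf.predict(x_te)
        np.testing.assert_array_equal(preds_before, preds_after)
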