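"""Normalisation, feature selection, oversampling, splitting, the SVM loop
and the clinical metric suite."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from zot.phantom import make_labeled_cohort
from zot.protocol import (
    ConfusionCounts,
    MarginSvmClassifier,
    QuartileScaler,
    _stratified_folds,
    confusion_metrics,
    count_quadruples,
    filter_quadruples,
    kde_lhs_oversample,
    largest_remainder,
    lasso_screen,
    margin_stratified_split,
    normalize,
    rank_quadruples,
    roc_analysis,
    train_svm_protocol,
    univariate_screen,
)


class TestConfusionMetrics:
    def test_training_design_counts(self):
        # a 117-sample training confusion matrix with printed-table rounding
        m = confusion_metrics(ConfusionCounts(tp=36, tn=66, fp=8, fn=7)).printed()
        assert m["SN"] == 84 and m["SP"] == 89
        assert m["I"] == 0.73
        assert m["NPV"] == 90 and m["DOR"] == 42

    def test_holdout_design_counts(self):
        m = confusion_metrics(ConfusionCounts(tp=16, tn=28, fp=5, fn=3)).printed()
        assert m["I"] == 0.69 and m["DOR"] == 30

    def test_balanced_uninformative(self):
        m = confusion_metrics(ConfusionCounts(1, 1, 1, 1)).printed()
        assert m["SN"] == 50 and m["SP"] == 50 and m["I"] == 0.0 and m["DOR"] == 1

    def test_identities_hold_pre_rounding(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            tp, tn, fp, fn = rng.integers(1, 60, size=4)
            m = confusion_metrics(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            sn, sp = m.sn / 100, m.sp / 100
            assert m.informedness == pytest.approx(sn + sp - 1)
            assert m.dor == pytest.approx((sn * sp) / ((1 - sn) * (1 - sp)))

    def test_infinite_dor_without_continuity_correction(self):
        m = confusion_metrics(ConfusionCounts(tp=5, tn=5, fp=0, fn=2))
        assert math.isinf(m.dor)


class TestRocAnalysis:
    def test_perfect_separation(self):
        scores = np.array([0.1, 0.2, 0.3, 0.8, 0.9, 1.0])
        labels = np.array([0, 0, 0, 1, 1, 1])
        m, counts = roc_analysis(scores, labels)
        assert m.auc == 1.0 and m.informedness == pytest.approx(1.0)
        assert counts.fp == counts.fn == 0

    def test_auc_equals_mann_whitney_pairwise_count(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=60)
        labels = (rng.random(60) < 0.4).astype(int)
        labels[:2] = [0, 1]
        m, _ = roc_analysis(scores, labels)
        pos = scores[labels == 1][:, None]
        neg = scores[labels == 0][None, :]
        u = (pos > neg).sum() + 0.5 * (pos == neg).sum()
        assert m.auc == pytest.approx(u / (pos.size * neg.size))

    def test_null_scores_give_half_auc(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=1000)
        labels = (rng.random(1000) < 0.5).astype(int)
        m, _ = roc_analysis(scores, labels)
        assert abs(m.auc - 0.5) < 0.1

    def test_youden_cutoff_takes_lower_threshold_on_ties(self):
        scores = np.array([0.0, 1.0, 2.0, 3.0])
        labels = np.array([0, 0, 1, 1])
        m, _ = roc_analysis(scores, labels)
        assert m.youden_cutoff == 2.0


class TestQuartileScaler:
    def test_uniform_feature_standardised(self):
        rng = np.random.default_rng(5)
        X = rng.random((500, 3))
        Xt = QuartileScaler().fit(X).transform(X)
        np.testing.assert_allclose(Xt.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(Xt.std(axis=0), 1, atol=1e-9)

    def test_train_quartiles_map_to_unit_interval(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(200, 2))
        sc = QuartileScaler().fit(X)
        q = sc.quartile_transform(np.vstack([sc.q1_, sc.q3_]))
        np.testing.assert_allclose(q[0], 0.0, atol=1e-12)
        np.testing.assert_allclose(q[1], 1.0, atol=1e-12)

    def test_constant_feature_flagged_and_finite(self):
        X = np.column_stack([np.ones(20), np.arange(20.0)])
        sc = QuartileScaler().fit(X)
        assert sc.zero_iqr_[0] and not sc.zero_iqr_[1]
        assert np.all(np.isfinite(sc.transform(X)))

    def test_transform_frozen_after_fit(self):
        rng = np.random.default_rng(7)
        train, test = rng.normal(size=(100, 2)), rng.normal(size=(50, 2)) + 5
        sc = QuartileScaler().fit(train)
        before = sc.transform(test).copy()
        sc.transform(train)  # must not refit
        np.testing.assert_array_equal(sc.transform(test), before)


class TestLargestRemainder:
    def test_exact_design_apportionments(self):
        np.testing.assert_array_equal(largest_remainder(117, np.array([62, 107])), [43, 74])
        np.testing.assert_array_equal(largest_remainder(52, np.array([19 + 0, 33])), [19, 33])

    def test_parts_sum_to_total(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            w = rng.integers(1, 50, size=4)
            assert largest_remainder(33, w).sum() == 33


class TestCountAndFilterQuadruples:
    @pytest.mark.parametrize("n,expected", [(19, 3876), (18, 3060), (16, 1820), (13, 715), (4, 1)])
    def test_binomial_counts(self, n, expected):
        assert count_quadruples(n) == expected

    def test_fewer_than_four_rejected(self):
        with pytest.raises(ValueError):
            count_quadruples(3)

    def test_independent_features_survive(self):
        t = make_labeled_cohort(300, 300, n_features=4, seed=9)
        X = t.drop(columns="label")
        quads = [tuple(X.columns)]
        assert filter_quadruples(quads, X, rho=0.3) == quads

    def test_duplicated_feature_discarded(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        X["d"] = X["a"]
        assert filter_quadruples([("a", "b", "c", "d")], X) == []

    def test_boundary_correlation_discarded(self):
        # construct two features with sample correlation exactly 0.3
        n = 40
        u = np.tile([1.0, -1.0], n // 2)
        v = np.tile([1.0, 1.0, -1.0, -1.0], n // 4)
        assert abs(np.corrcoef(u, v)[0, 1]) < 1e-12
        y = 0.3 * u + np.sqrt(1 - 0.09) * v
        rng = np.random.default_rng(11)
        X = pd.DataFrame({"a": u, "b": y, "c": rng.normal(size=n), "d": rng.normal(size=n)})
        assert np.corrcoef(X["a"], X["b"])[0, 1] == pytest.approx(0.3)
        assert filter_quadruples([("a", "b", "c", "d")], X, rho=0.3) == []


class TestRankQuadruples:
    def test_signal_quadruple_beats_noise(self):
        t = make_labeled_cohort(60, 60, effect_size=[2, 2, 2, 2, 0, 0, 0, 0], n_features=8, seed=12)
        X, y = t.drop(columns="label"), t["label"].to_numpy()
        quads = [tuple(X.columns[:4]), tuple(X.columns[4:])]
        best = rank_quadruples(quads, X, y, alpha=1e-3)
        assert best is not None
        assert best.features == tuple(X.columns[:4])

    def test_permuted_labels_rarely_significant(self):
        t = make_labeled_cohort(30, 30, n_features=4, seed=13)
        X = t.drop(columns="label")
        rng = np.random.default_rng(13)
        hits = 0
        for _ in range(30):
            y = rng.permutation(t["label"].to_numpy())
            if rank_quadruples([tuple(X.columns)], X, y, alpha=1e-3) is not None:
                hits += 1
        assert hits <= 1

    def test_holm_rejections_subset_of_unadjusted(self):
        t = make_labeled_cohort(40, 40, effect_size=1.0, n_features=8, seed=14)
        X, y = t.drop(columns="label"), t["label"].to_numpy()
        from itertools import combinations

        quads = list(combinations(X.columns, 4))[:20]
        best = rank_quadruples(quads, X, y, alpha=1e-3)
        if best is not None:
            assert best.n_significant <= best.n_tested


class TestLassoScreen:
    def test_informative_feature_retained(self):
        rng = np.random.default_rng(15)
        kept = 0
        for seed in range(10):
            t = make_labeled_cohort(50, 50, effect_size=[3] + [0] * 9, n_features=10, seed=seed)
            sel = lasso_screen(t.drop(columns="label"), t["label"], seed=seed)
            kept += "f000" in sel
        assert kept >= 9

    def test_duplicate_of_informative_feature_partially_retained(self):
        t = make_labeled_cohort(60, 60, effect_size=[3] + [0] * 5, n_features=6, seed=16)
        X = t.drop(columns="label")
        X["dup"] = X["f000"] + 1e-6
        sel = lasso_screen(X, t["label"], seed=16)
        assert "f000" in sel or "dup" in sel

    def test_null_features_mostly_dropped(self):
        counts = []
        for seed in range(10):
            t = make_labeled_cohort(50, 50, n_features=10, seed=100 + seed)
            counts.append(len(lasso_screen(t.drop(columns="label"), t["label"], seed=seed)))
        assert np.median(counts) <= 2


class TestKdeLhsOversample:
    def test_identity_when_target_equals_n(self):
        t = make_labeled_cohort(10, 15, n_features=3, seed=17)
        X, y = t.drop(columns="label"), t["label"].to_numpy()
        Xa, ya = kde_lhs_oversample(X, y, target_total=25, runs=5, seed=0)
        assert len(Xa) == 25
        np.testing.assert_array_equal(Xa.values[:25], X.values)

    def test_reference_design_class_targets(self):
        t = make_labeled_cohort(32, 57, n_features=4, seed=18)
        X, y = t.drop(columns="label"), t["label"].to_numpy()
        Xa, ya = kde_lhs_oversample(X, y, class_targets={1: 62, 0: 107}, runs=20, seed=0)
        assert len(Xa) == 169
        assert (ya == 1).sum() == 62 and (ya == 0).sum() == 107

    def test_correlation_preserved_in_augmented_table(self):
        corr = np.array([[1.0, 0.6], [0.6, 1.0]])
        t = make_labeled_cohort(60, 60, n_features=2, correlation=corr, seed=19)
        X, y = t.drop(columns="label"), t["label"].to_numpy()
        Xa, ya = kde_lhs_oversample(X, y, target_total=240, runs=50, seed=1)
        r = np.corrcoef(Xa.values, rowvar=False)[0, 1]
        assert abs(r - 0.6) <= 0.1

    def test_synthetic_values_within_kde_support(self):
        t = make_labeled_cohort(20, 20, n_features=2, seed=20)
        X, y = t.drop(columns="label"), t["label"].to_numpy()
        Xa, _ = kde_lhs_oversample(X, y, target_total=60, runs=5, seed=2)
        span = X.values.max() - X.values.min()
        assert Xa.values.min() >= X.values.min() - span
        assert Xa.values.max() <= X.values.max() + span

    def test_target_below_count_rejected(self):
        t = make_labeled_cohort(10, 10, n_features=2, seed=21)
        with pytest.raises(ValueError):
            kde_lhs_oversample(t.drop(columns="label"), t["label"].to_numpy(), target_total=15)


class TestMarginStratifiedSplit:
    def test_reference_train_test_bookkeeping(self):
        t = make_labeled_cohort(62, 107, effect_size=1.0, n_features=4, seed=22)
        X, y = t.drop(columns="label"), t["label"].to_numpy()
        plan = margin_stratified_split(X, y, train_n=117, seed=0)
        assert plan.train_counts == {1: 43, 0: 74}
        assert plan.test_counts == {1: 19, 0: 33}
        assert len(plan.train_idx) + len(plan.test_idx) == 169
        assert not set(plan.train_idx) & set(plan.test_idx)

    def test_margin_classes_preserved_proportionally(self):
        t = make_labeled_cohort(62, 107, effect_size=1.0, n_features=4, seed=23)
        X, y = t.drop(columns="label"), t["label"].to_numpy()
        plan = margin_stratified_split(X, y, train_n=117, seed=1)
        for c in (0, 1):
            for g in np.unique(plan.margin_class):
                total = ((y == c) & (plan.margin_class == g)).sum()
                if total < 3:
                    continue
                in_train = ((y[plan.train_idx] == c) & (plan.margin_class[plan.train_idx] == g)).sum()
                assert abs(in_train / total - 117 / 169) < 0.25

    def test_leave_one_out_split(self):
        t = make_labeled_cohort(10, 10, n_features=3, seed=24)
        X, y = t.drop(columns="label"), t["label"].to_numpy()
        plan = margin_stratified_split(X, y, train_n=19, seed=0)
        assert len(plan.test_idx) == 1

    def test_invalid_train_n(self):
        t = make_labeled_cohort(5, 5, n_features=2, seed=25)
        with pytest.raises(ValueError):
            margin_stratified_split(t.drop(columns="label"), t["label"].to_numpy(), train_n=10)


class TestStratifiedFolds:
    def test_reference_fold_sizes(self):
        y = np.array([1] * 43 + [0] * 74)
        assign = _stratified_folds(y, 3, np.random.default_rng(0))
        sizes = [(assign == f).sum() for f in range(3)]
        pos = sorted((assign[y == 1] == f).sum() for f in range(3))
        assert sizes == [39, 39, 39]
        assert pos == [14, 14, 15]


class TestTrainSvmProtocol:
    def test_separable_data_high_informedness(self):
        t = make_labeled_cohort(40, 40, effect_size=[3, 3, 0, 0], n_features=4, seed=26)
        X, y = t.drop(columns="label"), t["label"].to_numpy()
        model = train_svm_protocol(X, y, runs=5, tune_evals=6, seed=0)
        assert model.train_metrics.informedness >= 0.9

    def test_deterministic_under_seed(self):
        t = make_labeled_cohort(30, 30, effect_size=[1.5, 0, 0, 0], n_features=4, seed=27)
        X, y = t.drop(columns="label"), t["label"].to_numpy()
        a = train_svm_protocol(X, y, runs=3, tune_evals=4, seed=5)
        b = train_svm_protocol(X, y, runs=3, tune_evals=4, seed=5)
        assert a.gamma == b.gamma and a.C == b.C
        assert a.train_metrics == b.train_metrics

    def test_estimator_front_end(self):
        t = make_labeled_cohort(30, 30, effect_size=[2, 2, 0, 0], n_features=4, seed=28)
        X, y = t.drop(columns="label").values, t["label"].to_numpy()
        clf = MarginSvmClassifier(runs=3, tune_evals=4, seed=0).fit(X, y)
        proba = clf.predict_proba(X)
        assert proba.shape == (60, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        acc = (clf.predict(X) == y).mean()
        assert acc >= 0.9
        assert clf.get_params()["runs"] == 3


class TestUnivariateScreen:
    def test_single_shifted_feature_selected(self):
        t = make_labeled_cohort(18, 28, effect_size=[2.5] + [0] * 7, n_features=8, seed=29)
        Xn, _ = normalize(t.drop(columns="label"))
        res = univariate_screen(Xn, t["label"].to_numpy(), alpha=0.05)
        assert res is not None and res.feature == "f000"
        assert res.metrics.informedness > 0.3
        assert res.p_adjusted < 0.05

    def test_null_data_usually_empty(self):
        hits = 0
        for seed in range(20):
            t = make_labeled_cohort(18, 28, n_features=10, seed=200 + seed)
            res = univariate_screen(t.drop(columns="label"), t["label"].to_numpy())
            hits += res is not None
        assert hits <= 2

    def test_small_class_rejected(self):
        t = make_labeled_cohort(1, 10, n_features=3, seed=30)
        with pytest.raises(ValueError):
            univariate_screen(t.drop(columns="label"), t["label"].to_numpy())
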