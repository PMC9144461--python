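"""Cross-validation bookkeeping, ANOVA, Duncan's multiple range test, and
confusion-matrix metrics."""

import numpy as np
import pytest
from scipy.stats import f_oneway

from emgdecode import evaluation, models
from emgdecode.evaluation import (anova1, confusion_matrix,
                                  confusion_metrics, cv_partition, duncan,
                                  duncan_ranges, nested_cv_10x10)

from conftest import gaussian_blobs


class TestCvPartition:
    def test_equal_fold_sizes(self):
        folds = cv_partition(100, 10, seed=0)
        assert np.bincount(folds).tolist() == [10] * 10

    def test_partition_covers_everything_once(self):
        y = np.repeat(np.arange(1, 6), 13)
        folds = cv_partition(len(y), 5, seed=1, labels=y)
        assert folds.shape == (65,)
        assert set(np.unique(folds)) == set(range(5))
        for c in range(1, 6):
            sizes = np.bincount(folds[y == c], minlength=5)
            assert sizes.max() - sizes.min() <= 1

    def test_deterministic(self):
        y = np.repeat([1, 2], 30)
        a = cv_partition(60, 10, seed=7, labels=y)
        b = cv_partition(60, 10, seed=7, labels=y)
        assert np.array_equal(a, b)

    def test_small_class_rejected(self):
        y = np.array([1] * 20 + [2] * 3)
        with pytest.raises(ValueError, match="class 2"):
            cv_partition(23, 10, seed=0, labels=y)


class TestNestedCv:
    def test_separable_data_scores_100(self):
        X, y = gaussian_blobs(n_classes=3, n_per_class=40, d=4, seed=0,
                              separation=20.0)
        rep = nested_cv_10x10(X, y, "qda", "B", seed=0)
        assert rep.trn == rep.val == rep.tst == 100.0

    def test_averages_are_fold_means(self):
        X, y = gaussian_blobs(n_classes=3, n_per_class=40, d=4, seed=1,
                              separation=1.0)
        rep = nested_cv_10x10(X, y, "lda", "D", seed=1)
        assert rep.tst == pytest.approx(np.mean(rep.fold_tst))
        assert rep.trn == pytest.approx(np.mean(rep.fold_trn))
        assert rep.val == pytest.approx(np.mean(rep.fold_val))
        assert len(rep.fold_tst) == 10
        assert all(0 <= v <= 100 for v in rep.fold_tst)

    def test_chance_level_on_permuted_labels(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((600, 4))
        y = np.repeat(np.arange(1, 16), 40)
        rng.shuffle(y)
        rep = nested_cv_10x10(X, y, "lda", "D", seed=2)
        assert rep.tst == pytest.approx(100 / 15, abs=4.0)

    def test_sfs_treatment_records_subset_size(self):
        X, y = gaussian_blobs(n_classes=3, n_per_class=40, d=6, seed=3,
                              separation=2.0)
        rep = nested_cv_10x10(X, y, "qda", "A", seed=3)
        assert 1 <= rep.n_features <= 6
        assert rep.sfs_subset is not None

    def test_no_leakage_with_outer_fold_sfs(self):
        """Perturbing rows of one outer test fold must not change the
        feature subset selected inside that fold's training block."""
        X, y = gaussian_blobs(n_classes=3, n_per_class=40, d=5, seed=4,
                              separation=1.5)
        outer = cv_partition(len(y), 10, seed=5, labels=y)
        tst = outer == 0
        from emgdecode.preprocess import normalize_apply, normalize_fit
        from emgdecode.selection import sfs

        def subset_for(Xfull):
            Xtv = Xfull[~tst]
            Xn = normalize_apply(normalize_fit(Xtv), Xtv)
            return sfs(Xn, y[~tst], model_kind="qda").subset

        X_perturbed = X.copy()
        X_perturbed[tst] += 100.0
        assert subset_for(X) == subset_for(X_perturbed)


class TestAnova:
    def test_matches_scipy_and_two_pass_oracle(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(loc, 2.0, size=12) for loc in (0, 1, 3)]
        res = anova1(groups)
        ref = f_oneway(*groups)
        assert res.F == pytest.approx(ref.statistic, abs=1e-9)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)
        # independent two-pass sum-of-squares computation
        allv = np.concatenate(groups)
        ss_total = ((allv - allv.mean()) ** 2).sum()
        assert res.SS_between + res.SS_within == pytest.approx(ss_total,
                                                               abs=1e-9)
        assert res.df_between == 2
        assert res.df_within == len(allv) - 3

    def test_identical_groups_give_zero_F(self):
        g = np.ones(5)
        res = anova1([g, g])
        assert res.F == 0.0

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            anova1([np.ones(3)])


class TestDuncan:
    def test_range_values_match_published_tables(self):
        # classical Duncan significant-range table entries, alpha = 0.05
        assert duncan_ranges(2, 20) == pytest.approx(2.95, abs=0.01)
        assert duncan_ranges(3, 20) == pytest.approx(3.10, abs=0.01)
        assert duncan_ranges(2, 10) == pytest.approx(3.15, abs=0.01)
        assert duncan_ranges(4, 30) == pytest.approx(3.12, abs=0.02)

    def test_ranges_non_decreasing_in_span(self):
        rng = np.random.default_rng(6)
        groups = [rng.normal(k, 1.0, 8) for k in range(4)]
        res = duncan(groups)
        values = [res.ranges[p] for p in sorted(res.ranges)]
        assert values == sorted(values)

    def test_equal_means_not_significant(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 10)
        b = rng.normal(0, 1, 10)
        res = duncan([a, b], names=["a", "b"])
        assert res.significant[frozenset({"a", "b"})] is False

    def test_separated_group_flagged(self):
        # identical within-group spread; means 0, 0.1 and 25 exactly
        base = np.array([-1.5, -1.0, -0.5, 0.0, 0.0, 0.5, 1.0, 1.5])
        groups = [base, base + 0.1, base + 25.0]
        res = duncan(groups, names=["a", "b", "c"])
        assert res.significant[frozenset({"a", "c"})]
        assert res.significant[frozenset({"b", "c"})]
        assert not res.significant[frozenset({"a", "b"})]

    def test_containment_rule(self):
        """No pair inside a non-significant span may be significant."""
        rng = np.random.default_rng(9)
        for trial in range(20):
            groups = [rng.normal(rng.uniform(0, 4), 1.0, 6)
                      for _ in range(5)]
            res = duncan(groups)
            pos = {nm: i for i, nm in enumerate(res.order)}
            for pair, sig in res.significant.items():
                if sig:
                    continue
                a, b = sorted(pair, key=lambda nm: pos[nm])
                inner = [nm for nm in res.order
                         if pos[a] <= pos[nm] <= pos[b]]
                for i, x in enumerate(inner):
                    for z in inner[i + 1:]:
                        assert not res.significant[frozenset({x, z})]

    def test_unequal_sizes_rejected(self):
        with pytest.raises(ValueError, match="equal group sizes"):
            duncan([np.ones(5), np.ones(6)])


class TestConfusionMetrics:
    def test_perfect_diagonal(self):
        cm = np.diag([5, 8, 9])
        m = confusion_metrics(cm)
        for key in ("sensitivity", "specificity", "precision", "f1"):
            np.testing.assert_allclose(m[key], 100.0)

    def test_binary_worked_example(self):
        # TP 8, FN 2, FP 1, TN 9 for class 1
        cm = np.array([[8, 2], [1, 9]])
        m = confusion_metrics(cm)
        assert m["sensitivity"][0] == pytest.approx(80.0)
        assert m["precision"][0] == pytest.approx(88.888888, abs=1e-4)
        assert m["f1"][0] == pytest.approx(84.210526, abs=1e-4)
        assert m["specificity"][0] == pytest.approx(90.0)

    def test_absent_class_warns_not_crashes(self):
        cm = np.array([[10, 0, 0], [0, 10, 0], [0, 0, 0]])
        with pytest.warns(UserWarning):
            m = confusion_metrics(cm)
        assert m["sensitivity"][2] == 0.0
        assert m["precision"][2] == 0.0

    def test_counts_conserved(self):
        rng = np.random.default_rng(10)
        truth = rng.integers(1, 5, 200)
        pred = rng.integers(1, 5, 200)
        cm = confusion_matrix(truth, pred)
        assert cm.sum() == 200
        m = confusion_metrics(cm)
        for i in range(4):
            assert m["tp"][i] + m["fp"][i] + m["tn"][i] + m["fn"][i] == 200


class TestExperimentGrid:
    def test_tiny_grid_shape_and_determinism(self):
        per_subject = [gaussian_blobs(n_classes=3, n_per_class=20, d=4,
                                      seed=s, separation=2.0)
                       for s in (20, 21)]
        pooled = (np.concatenate([X for X, _ in per_subject]),
                  np.concatenate([y for _, y in per_subject]))
        kwargs = dict(kinds=("qda",), treatments=("B", "D"), seed=5)
        a = evaluation.run_experiment_grid(per_subject, pooled, **kwargs)
        b = evaluation.run_experiment_grid(per_subject, pooled, **kwargs)
        assert set(a.reports) == {("qda", tr, sc)
                                  for tr in ("B", "D")
                                  for sc in ("sub1", "sub2", "pooled")}
        for key in a.reports:
            assert a.reports[key].tst == b.reports[key].tst
        assert a.anova is not None
        assert a.anova.F == b.anova.F
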