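"""Outlier elimination, windowing, the 12 time-domain features, and
normalization — including the independent numerical oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emgdecode import preprocess
from emgdecode.preprocess import (FeatureParams, chi2_critical, features12,
                                  feature_matrix, make_windows,
                                  mahalanobis_sq, normalize_apply,
                                  normalize_fit, remove_outliers)

# ---------------------------------------------------------------- oracles


def _mahalanobis_brute(x, mean, inv_cov):
    """Explicit double-loop quadratic form."""
    d = x - mean
    total = 0.0
    for i in range(len(d)):
        for j in range(len(d)):
            total += d[i] * inv_cov[i, j] * d[j]
    return total


def _reg_gamma_lower(a, x, terms=500):
    """Regularized lower incomplete gamma P(a, x) by its power series."""
    import math
    if x <= 0:
        return 0.0
    total = 0.0
    term = 1.0 / a
    for n in range(1, terms + 1):
        total += term
        term *= x / (a + n)
        if term < 1e-18 * total:
            break
    return total * math.exp(-x + a * math.log(x) - math.lgamma(a))


def _chi2_ppf_oracle(df, p, lo=0.0, hi=1000.0, iters=200):
    """Bisection on the chi-square CDF, P(df/2, x/2)."""
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if _reg_gamma_lower(df / 2.0, mid / 2.0) < p:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ----------------------------------------------------------- mahalanobis


class TestMahalanobis:
    def test_zero_at_mean_and_euclidean_reduction(self):
        x = np.arange(8.0)
        assert mahalanobis_sq(x, x, np.eye(8)) == 0.0
        y = x + 2.0
        assert mahalanobis_sq(y, x, np.eye(8)) == pytest.approx(8 * 4.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            x, mean = rng.standard_normal((2, 8))
            A = rng.standard_normal((8, 8))
            inv_cov = A @ A.T + np.eye(8)
            assert mahalanobis_sq(x, mean, inv_cov) == pytest.approx(
                _mahalanobis_brute(x, mean, inv_cov), abs=1e-10)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mahalanobis_sq(np.zeros(3), np.zeros(8), np.eye(8))


class TestChi2Critical:
    def test_df2_median_is_2ln2(self):
        assert chi2_critical(2, 0.5) == pytest.approx(2 * np.log(2),
                                                      abs=1e-9)

    def test_monotone_in_p(self):
        assert chi2_critical(8, 0.99) > chi2_critical(8, 0.95)

    @pytest.mark.parametrize("df,p", [(8, 0.95), (8, 0.999), (2, 0.9),
                                      (15, 0.99)])
    def test_matches_incomplete_gamma_inversion(self, df, p):
        assert chi2_critical(df, p) == pytest.approx(
            _chi2_ppf_oracle(df, p), abs=1e-6)

    def test_invalid_p_rejected(self):
        for p in (0.0, 1.0, -0.1, 1.1):
            with pytest.raises(ValueError):
                chi2_critical(8, p)


class TestRemoveOutliers:
    def _labeled_mvn(self, n, seed=0):
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((8, 8)) * 0.3 + np.eye(8)
        X = rng.standard_normal((n, 8)) @ A.T
        return np.column_stack([X, np.ones(n)])

    def test_chi2_coverage_on_clean_gaussian(self):
        m = self._labeled_mvn(50_000, seed=1)
        kept, report = remove_outliers(m, p=0.99)
        n, p_out = m.shape[0], 0.01
        sd = np.sqrt(n * p_out * (1 - p_out))
        assert abs(report.removed_rows - n * p_out) <= 4 * sd
        assert report.kept_rows + report.removed_rows == report.total_rows
        assert len(kept) == report.kept_rows

    def test_p_near_one_removes_nothing(self):
        m = self._labeled_mvn(2000, seed=2)
        _, report = remove_outliers(m, p=1 - 1e-12)
        assert report.removed_rows == 0

    def test_injected_artifacts_removed(self):
        """The stage removes exactly the rows an independent Mahalanobis
        computation flags, and that covers the bulk of injected artifacts
        (a x50 spike on a near-zero sample is legitimately not an
        outlier, and the artifacts themselves inflate the covariance)."""
        from emgdecode.synthgen import ArtifactSpec, inject_artifacts
        m = self._labeled_mvn(20_000, seed=3)
        corrupted, mask = inject_artifacts(m[:, :8],
                                           ArtifactSpec(0.02, 50.0, seed=4))
        m2 = np.column_stack([corrupted, m[:, 8]])
        kept, report = remove_outliers(m2, p=0.999)
        # independent distance computation over the same rows
        X = m2[:, :8]
        mean = X.mean(axis=0)
        inv_cov = np.linalg.inv(np.cov(X, rowvar=False))
        diff = X - mean
        d2 = np.einsum("ij,jk,ik->i", diff, inv_cov, diff)
        expected_keep = d2 <= report.threshold
        assert report.kept_rows == pytest.approx(expected_keep.sum(), abs=2)
        removed_artifact_frac = 1 - expected_keep[mask].mean()
        assert report.removed_rows >= 0.95 * (~expected_keep).sum()
        assert removed_artifact_frac >= 0.6

    def test_per_stratum_counts_conserve(self):
        rng = np.random.default_rng(5)
        m = self._labeled_mvn(4000, seed=5)
        m[:2000, 8] = 2  # two movements
        subject_ids = np.repeat([1, 2], 2000)
        _, report = remove_outliers(m, p=0.99, subject_ids=subject_ids)
        for d in (*report.per_movement.values(),
                  *report.per_subject.values()):
            assert d["kept"] + d["removed"] == d["total"]
        assert sum(d["total"] for d in report.per_movement.values()) \
            == report.total_rows

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            remove_outliers(np.zeros((5, 9)))


# -------------------------------------------------------------- windowing


class TestMakeWindows:
    def _labeled(self, n, label):
        return np.column_stack([np.random.default_rng(0).standard_normal(
            (n, 8)), np.full(n, float(label))])

    def test_repetition_yields_80_windows(self):
        windows = make_windows(self._labeled(20_000, 1), 250)
        assert len(windows) == 80
        assert all(w.shape == (250, 8) and lab == 1 for w, lab in windows)

    def test_remainder_rule(self):
        sizes = [w.shape[0] for w, _ in make_windows(self._labeled(501, 2),
                                                     250)]
        assert sizes == [250, 250, 1]

    def test_windows_never_span_class_change(self):
        m = np.concatenate([self._labeled(300, 1), self._labeled(300, 2)])
        windows = make_windows(m, 250)
        assert [(w.shape[0], lab) for w, lab in windows] == [
            (250, 1), (50, 1), (250, 2), (50, 2)]

    def test_partition_property(self):
        m = np.concatenate([self._labeled(n, lab)
                            for lab, n in ((1, 777), (2, 250), (3, 13))])
        windows = make_windows(m, 250)
        assert sum(w.shape[0] for w, _ in windows) == len(m)


# --------------------------------------------------------------- features


class TestFeatures12:
    def test_hand_worked_example(self):
        f = features12(np.array([1.0, -1.0, 2.0]),
                       FeatureParams(0.0, 0.0, 0.0))
        names = preprocess.FEATURE_NAMES
        vals = dict(zip(names, f))
        assert vals["MAV"] == pytest.approx(4 / 3)
        assert vals["SSI"] == pytest.approx(6.0)
        assert vals["WL"] == pytest.approx(5.0)
        assert vals["ZC"] == 2
        assert vals["SSC"] == 1
        assert vals["MYOP"] == 1.0

    def test_constant_signal(self):
        c = 3.0
        n = 10
        f = dict(zip(preprocess.FEATURE_NAMES,
                     features12(np.full(n, c), FeatureParams(0, 0, 0))))
        assert f["VAR"] == pytest.approx(n * c * c / (n - 1))
        assert f["WL"] == 0 and f["ZC"] == 0 and f["SSC"] == 0

    def test_algebraic_identities(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(250)
        f = dict(zip(preprocess.FEATURE_NAMES, features12(x)))
        assert f["RMS"] ** 2 == pytest.approx(f["MSV"], abs=1e-10)
        assert f["SSI"] == pytest.approx(250 * f["MSV"], abs=1e-8)

    def test_sign_symmetry(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(100)
        fa = features12(x, FeatureParams(0, 0, 0.1))
        fb = features12(-x, FeatureParams(0, 0, 0.1))
        np.testing.assert_allclose(fa, fb, atol=1e-12)

    def test_scaling_behaviour(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(128)
        c = 2.5
        names = preprocess.FEATURE_NAMES
        fa = dict(zip(names, features12(x, FeatureParams(0, 0, 0))))
        fb = dict(zip(names, features12(c * x, FeatureParams(0, 0, 0))))
        for lin in ("MAV", "RMS", "WL"):
            assert fb[lin] == pytest.approx(abs(c) * fa[lin])
        for quad in ("MSV", "SSI", "VAR"):
            assert fb[quad] == pytest.approx(c * c * fa[quad])

    def test_permutation_invariant_subset(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(64)
        xp = rng.permutation(x)
        names = preprocess.FEATURE_NAMES
        fa = dict(zip(names, features12(x, FeatureParams(0, 0, 0.5))))
        fb = dict(zip(names, features12(xp, FeatureParams(0, 0, 0.5))))
        for inv in ("MAV", "MSV", "SSI", "RMS", "VAR", "MYOP"):
            assert fb[inv] == pytest.approx(fa[inv], abs=1e-12)

    def test_single_sample_window_rules(self):
        f = dict(zip(preprocess.FEATURE_NAMES,
                     features12(np.array([2.0]), FeatureParams(0, 0, 0))))
        assert f["VAR"] == 0 and f["WL"] == 0
        assert f["ZC"] == 0 and f["SSC"] == 0
        assert f["MAV"] == 2.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            features12(np.array([]))


class TestFeatureMatrix:
    def test_row_length_and_count(self):
        rng = np.random.default_rng(11)
        windows = [(rng.standard_normal((250, 8)), 3) for _ in range(80)]
        X, y = feature_matrix(windows)
        assert X.shape == (80, 96)
        assert (y == 3).all()
        assert len(preprocess.feature_names()) == 96

    def test_channel_major_order(self):
        rng = np.random.default_rng(12)
        w = rng.standard_normal((100, 8))
        X, _ = feature_matrix([(w, 1)], FeatureParams(0, 0, 0))
        perm = [3, 0, 1, 2, 4, 5, 6, 7]
        Xp, _ = feature_matrix([(w[:, perm], 1)], FeatureParams(0, 0, 0))
        blocks = X.reshape(8, 12)
        blocks_p = Xp.reshape(8, 12)
        np.testing.assert_allclose(blocks_p, blocks[perm], atol=1e-12)


# ----------------------------------------------------------- normalization


class TestNormalization:
    def test_training_data_standardized(self):
        rng = np.random.default_rng(13)
        X = rng.standard_normal((200, 10)) * 5 + 3
        model = normalize_fit(X)
        Z = normalize_apply(model, X)
        np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(Z.std(axis=0, ddof=1), 1, atol=1e-9)

    def test_constant_feature_maps_to_zero(self):
        X = np.ones((50, 3))
        X[:, 1] = np.random.default_rng(14).standard_normal(50)
        Z = normalize_apply(normalize_fit(X), X)
        assert (Z[:, 0] == 0).all() and (Z[:, 2] == 0).all()

    def test_uses_training_statistics_only(self):
        """Shifting the training set shifts held-out outputs identically —
        statistics must not be re-estimated on the applied rows."""
        rng = np.random.default_rng(15)
        train = rng.standard_normal((100, 4))
        held = rng.standard_normal((30, 4))
        za = normalize_apply(normalize_fit(train), held)
        zb = normalize_apply(normalize_fit(train + 7.0), held)
        np.testing.assert_allclose(zb, za - 7.0 / train.std(axis=0, ddof=1),
                                   atol=1e-9)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            normalize_fit(np.zeros((1, 3)))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(1, 400), st.integers(1, 250), st.integers(0, 2**31 - 1))
def test_window_partition_property(n, window_len, seed):
    """Windows always partition a block exactly, whatever its size."""
    rng = np.random.default_rng(seed)
    m = np.column_stack([rng.standard_normal((n, 8)), np.ones(n)])
    windows = make_windows(m, window_len)
    sizes = [w.shape[0] for w, _ in windows]
    assert sum(sizes) == n
    assert all(1 <= s <= window_len for s in sizes)
    if sizes:
        assert all(s == window_len for s in sizes[:-1])
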