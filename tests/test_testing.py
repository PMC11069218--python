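"""Test statistics, p-values, multigroup and Nystrom paths."""

import numpy as np
import pytest
import scipy.stats

from kfdiff import (
    Dataset,
    KernelSpec,
    asymptotic_pvalue,
    bh_adjust,
    diff_coordinates,
    gauss_gram,
    kfda_statistic,
    linear_gram,
    mmd2,
    multigroup_test,
    nystrom_reduce,
    permutation_test,
    two_sample_test,
    univariate_all,
    within_spectrum,
)
from kfdiff.simulate import DEFAULT_CATALOG, simulate_gene

from test_embedding import pooled_within_cov


class TestMMD2:
    def test_identical_samples_zero(self, rng):
        X = rng.normal(size=(8, 2))
        ds = Dataset(np.vstack([X, X]), ["a"] * 8 + ["b"] * 8)
        assert abs(mmd2(gauss_gram(ds, KernelSpec(bandwidth=1.0)), ds.condition)) < 1e-12

    def test_brute_force_double_sum(self, rng):
        y = rng.normal(size=9)
        ds = Dataset(y[:, None], ["a"] * 4 + ["b"] * 5)
        gram = gauss_gram(ds, KernelSpec(bandwidth=0.8))
        K = gram.values
        s11 = sum(K[a, b] for a in range(4) for b in range(4)) / 16
        s22 = sum(K[a, b] for a in range(4, 9) for b in range(4, 9)) / 25
        s12 = sum(K[a, b] for a in range(4) for b in range(4, 9)) / 20
        assert mmd2(gram, ds.condition) == pytest.approx(s11 + s22 - 2 * s12, abs=1e-12)

    def test_nonnegative(self, gaussian_pair):
        for seed in range(5):
            ds = gaussian_pair(n1=7, n2=9, shift=0.0, seed=seed)
            assert mmd2(gauss_gram(ds, KernelSpec(bandwidth=1.0)), ds.condition) >= -1e-10


class TestKfdaStatistic:
    def test_hotelling_equivalence_bivariate(self, gaussian_pair):
        ds = gaussian_pair(n1=50, n2=50, p=2, shift=0.6, seed=21)
        gram = linear_gram(ds)
        dec = within_spectrum(gram, ds.condition, T=2)
        diff = diff_coordinates(gram, ds.condition, dec)
        stat = kfda_statistic(dec, diff)[2]
        X, codes = ds.values, ds.condition.cat.codes.to_numpy()
        S = pooled_within_cov(X, codes)
        d = X[codes == 1].mean(axis=0) - X[codes == 0].mean(axis=0)
        hotelling = 50 * 50 / 100 * d @ np.linalg.solve(S, d)
        assert stat == pytest.approx(hotelling, abs=1e-8)

    def test_monotone_in_truncation(self, gaussian_pair):
        for seed in range(10):
            ds = gaussian_pair(n1=15, n2=15, p=3, shift=0.3, seed=seed)
            res = two_sample_test(ds, KernelSpec(bandwidth=1.0), T=6, warn_small_n=False)
            vals = [res.statistic_by_t[t] for t in sorted(res.statistic_by_t)]
            assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_identical_samples_zero_for_all_t(self, rng):
        X = rng.normal(size=(10, 2))
        ds = Dataset(np.vstack([X, X]), ["a"] * 10 + ["b"] * 10)
        res = two_sample_test(ds, KernelSpec(bandwidth=1.0), T=4, warn_small_n=False)
        assert all(abs(v) < 1e-9 for v in res.statistic_by_t.values())

    def test_label_swap_leaves_statistic_unchanged(self, gaussian_pair):
        ds = gaussian_pair(n1=12, n2=14, seed=3)
        swapped = Dataset(ds.values, ["b" if l == "a" else "a" for l in ds.condition])
        spec = KernelSpec(bandwidth=1.1)
        r1 = two_sample_test(ds, spec, T=3, warn_small_n=False)
        r2 = two_sample_test(swapped, spec, T=3, warn_small_n=False)
        assert r1.statistic_by_t == pytest.approx(r2.statistic_by_t)
        assert r1.pvalue_asymptotic == pytest.approx(r2.pvalue_asymptotic)


class TestAsymptoticPvalue:
    def test_zero_statistic(self):
        assert asymptotic_pvalue(0.0, 4) == 1.0

    def test_chi2_quantile(self):
        assert asymptotic_pvalue(9.4877, 4) == pytest.approx(0.05, abs=1e-4)

    def test_large_statistic_vanishes(self):
        assert asymptotic_pvalue(1e4, 2) < 1e-300

    def test_invalid_df(self):
        with pytest.raises(ValueError):
            asymptotic_pvalue(1.0, 0)


class TestPermutation:
    def test_deterministic_given_seed(self, gaussian_pair):
        ds = gaussian_pair(n1=20, n2=20, shift=0.0, seed=10)
        r1 = permutation_test(ds, KernelSpec(bandwidth=1.0), T=3, B=50, seed=42)
        r2 = permutation_test(ds, KernelSpec(bandwidth=1.0), T=3, B=50, seed=42)
        assert r1.pvalue_permutation == r2.pvalue_permutation
        np.testing.assert_array_equal(r1.null_statistics, r2.null_statistics)

    def test_pvalue_lower_bound(self, rng):
        # univariate linear kernel with a massive mean shift: the observed
        # Hotelling-type statistic dwarfs every permuted one
        y = np.concatenate([rng.normal(0, 1, 25), rng.normal(8, 1, 25)])
        ds = Dataset(y[:, None], ["a"] * 25 + ["b"] * 25)
        res = permutation_test(ds, KernelSpec("linear", 1.0), T=1, B=99, seed=1)
        assert res.pvalue_permutation == pytest.approx(1.0 / 100.0)
        # and the reported p always matches the (1 + b)/(B + 1) estimator
        b = np.sum(res.null_statistics >= res.statistic_by_t[res.truncation])
        assert res.pvalue_permutation == pytest.approx((1 + b) / 100.0)

    def test_null_calibration_small(self):
        # both conditions same generator: p should rarely be small
        hits = 0
        reps = 40
        for r in range(reps):
            rng = np.random.default_rng(500 + r)
            X = rng.normal(size=(40, 2))
            ds = Dataset(X, ["a"] * 20 + ["b"] * 20)
            res = permutation_test(ds, KernelSpec(bandwidth="median"), T=3, B=200, seed=r)
            hits += res.pvalue_permutation > 0.05
        assert hits >= 0.85 * reps

    def test_seed_required(self, gaussian_pair):
        with pytest.raises(ValueError, match="seed"):
            permutation_test(gaussian_pair(), KernelSpec(bandwidth=1.0), T=2, B=10)


class TestMultigroup:
    def test_two_group_reduction(self, gaussian_pair):
        ds = gaussian_pair(n1=18, n2=22, shift=0.5, seed=13)
        spec = KernelSpec(bandwidth=1.4)
        gram = gauss_gram(ds, spec)
        dec = within_spectrum(gram, ds.condition, T=3)
        diff = diff_coordinates(gram, ds.condition, dec)
        two = kfda_statistic(dec, diff)[3]
        multi = multigroup_test(ds, spec, T=3, gram=gram)
        assert multi.statistic == pytest.approx(two, abs=1e-10)
        assert multi.df == 3

    def test_identical_groups_zero(self, rng):
        X = rng.normal(size=(8, 2))
        ds = Dataset(np.vstack([X, X, X]), ["a"] * 8 + ["b"] * 8 + ["c"] * 8)
        res = multigroup_test(ds, KernelSpec(bandwidth=1.0), T=3)
        assert res.statistic < 1e-9

    def test_three_group_linear_oracle(self, rng):
        X = np.vstack(
            [rng.normal(0, 1, (15, 2)), rng.normal(0.7, 1, (18, 2)), rng.normal(-0.4, 1, (17, 2))]
        )
        codes = np.array([0] * 15 + [1] * 18 + [2] * 17)
        ds = Dataset(X, [["a", "b", "c"][c] for c in codes])
        res = multigroup_test(ds, KernelSpec("linear", 1.0), T=2)
        n = len(codes)
        SW = pooled_within_cov(X, codes)
        m = X.mean(axis=0)
        SB = np.zeros((2, 2))
        for g in range(3):
            ng = (codes == g).sum()
            dg = X[codes == g].mean(axis=0) - m
            SB += ng / n * np.outer(dg, dg)
        oracle = n * np.trace(np.linalg.solve(SW, SB))
        assert res.statistic == pytest.approx(oracle, abs=1e-8)
        assert res.df == 4  # T=2 × (G−1)=2
        assert res.axis_coefficients.shape == (2, 2)

    def test_small_group_rejected(self, rng):
        ds = Dataset(rng.normal(size=(5, 1)), ["a", "a", "b", "b", "c"])
        with pytest.raises(ValueError):
            multigroup_test(ds, KernelSpec(bandwidth=1.0), T=1)


class TestNystrom:
    def test_full_landmarks_exact(self, gaussian_pair):
        ds = gaussian_pair(n1=30, n2=30, shift=0.5, seed=17)
        spec = KernelSpec(bandwidth=1.5)
        exact = two_sample_test(ds, spec, T=3, warn_small_n=False).statistic_by_t[3]
        red = nystrom_reduce(ds, spec, n_landmarks=60, seed=5)
        approx = two_sample_test(
            red, KernelSpec("linear", 1.0), T=3, warn_small_n=False
        ).statistic_by_t[3]
        assert approx == pytest.approx(exact, abs=1e-8)

    def test_fixed_seed_fixed_landmarks(self, gaussian_pair):
        ds = gaussian_pair(n1=25, n2=25, seed=18)
        r1 = nystrom_reduce(ds, KernelSpec(bandwidth=1.0), n_landmarks=20, seed=9)
        r2 = nystrom_reduce(ds, KernelSpec(bandwidth=1.0), n_landmarks=20, seed=9)
        np.testing.assert_array_equal(r1.values, r2.values)

    def test_reduction_approximates_statistic(self):
        # moderate reduction keeps the statistic in the right ballpark
        errs = []
        for seed in range(10):
            rng = np.random.default_rng(700 + seed)
            X = np.vstack([rng.normal(0, 1, (150, 2)), rng.normal(0.6, 1, (150, 2))])
            ds = Dataset(X, ["a"] * 150 + ["b"] * 150)
            spec = KernelSpec(bandwidth="median").resolve_bandwidth(ds)
            exact = two_sample_test(ds, spec, T=3, warn_small_n=False).statistic_by_t[3]
            red = nystrom_reduce(ds, spec, n_landmarks=100, seed=seed)
            approx = two_sample_test(
                red, KernelSpec("linear", 1.0), T=3, warn_small_n=False
            ).statistic_by_t[3]
            errs.append(abs(approx - exact) / exact)
        assert np.median(errs) < 0.15

    def test_too_few_landmarks_rejected(self, gaussian_pair):
        with pytest.raises(ValueError):
            nystrom_reduce(gaussian_pair(), KernelSpec(bandwidth=1.0),
                           n_landmarks=3, seed=1, T=4)


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_hand_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.04, 0.03, 0.005]), [0.02, 0.04, 0.04, 0.02]
        )
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.9]), [0.03, 0.03, 0.9])

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, np.nan])


class TestUnivariateAll:
    def test_table_shape_and_columns(self, rng):
        n = 30
        X = rng.poisson(4.0, size=(2 * n, 5)).astype(float)
        ds = Dataset(X, ["a"] * n + ["b"] * n)
        table = univariate_all(ds, KernelSpec(), T=4)
        assert len(table) == 5
        assert list(table.columns) == [
            "feature_id", "statistic", "df", "pvalue", "pvalue_adj",
            "n1", "n2", "pi1", "pi2", "mean1", "mean2", "flag",
        ]
        assert (table["pvalue_adj"] >= table["pvalue"] - 1e-12).all()

    def test_constant_feature_flagged_not_fatal(self, rng):
        n = 20
        X = np.column_stack([
            rng.poisson(4.0, 2 * n).astype(float), np.full(2 * n, 7.0),
        ])
        ds = Dataset(X, ["a"] * n + ["b"] * n)
        table = univariate_all(ds, KernelSpec(), T=4)
        row = table.set_index("feature_id").loc["f1"]
        assert row["flag"] == "degenerate" and row["pvalue"] == 1.0

    def test_null_rejection_rate_near_alpha(self):
        # 100 H0 genes: ≈ 5 rejections expected at α = 0.05
        y1, y2 = [], []
        for g in range(100):
            a, b = simulate_gene(
                DEFAULT_CATALOG["H0_unimodal"], 60, 60, np.random.SeedSequence([9, g])
            )
            y1.append(a)
            y2.append(b)
        X = np.column_stack([np.concatenate([a, b]) for a, b in zip(y1, y2)])
        ds = Dataset(X, ["a"] * 60 + ["b"] * 60)
        table = univariate_all(ds, KernelSpec(), T=4)
        ok = table[table.flag == "ok"]
        rate = (ok["pvalue"] < 0.05).mean()
        assert 0.0 <= rate <= 0.13  # 3σ binomial band around 0.05 at m=100

    def test_zi_gauss_mode_runs(self, rng):
        n = 25
        X = rng.poisson(2.0, size=(2 * n, 3)).astype(float)
        X[rng.random((2 * n, 3)) < 0.5] = 0.0
        ds = Dataset(X, ["a"] * n + ["b"] * n)
        table = univariate_all(ds, KernelSpec("zi_gauss"), T=4)
        assert len(table) == 3
        assert (table["pvalue"] <= 1).all() and (table["pvalue"] >= 0).all()
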