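"""Statistical engine: normalization, GLMs, moderation, utility tests."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_h
from scipy import special
from scipy import stats as sps

from chromdiff.stats import (
    CountMatrix,
    bh_adjust,
    cpm_filter,
    estimate_dispersion_trend,
    fisher_exact_2x2,
    fit_nb_glm,
    leading_logfc_distance,
    make_design,
    nb_deviance,
    ql_test,
    simes_p,
    squeeze_variances,
    tmm_factors,
    voom_weighted_lm,
    wilcoxon_rank_sum,
)


def _cm(counts, lib_sizes=None):
    counts = np.asarray(counts)
    return CountMatrix(counts, [f"s{i}" for i in range(counts.shape[1])],
                       lib_sizes=lib_sizes)


# ---------------------------------------------------------------------------
# TMM and CPM filtering
# ---------------------------------------------------------------------------


class TestTMM:
    def test_identical_columns_give_exact_ones(self, rng):
        col = rng.poisson(50, 500)
        f = tmm_factors(_cm(np.tile(col[:, None], (1, 2))))
        assert (f == 1.0).all()

    def test_pure_depth_change_absorbed_by_library_size(self, rng):
        col = rng.poisson(50, 500) + 1
        f = tmm_factors(_cm(np.column_stack([col, 2 * col])))
        np.testing.assert_allclose(f, [1.0, 1.0], atol=1e-12)

    def test_matches_brute_force_trimmed_mean(self, rng):
        col = rng.poisson(100, 2000) + 1
        col2 = col.copy()
        boosted = rng.choice(2000, 200, replace=False)
        col2[boosted] *= 8
        counts = np.column_stack([col, col2])
        cm = _cm(counts)
        f = tmm_factors(cm, ref=0)
        # independent oracle: explicit sort-based trim of M and A values
        lib = counts.sum(axis=0).astype(float)
        obs, ref = counts[:, 1].astype(float), counts[:, 0].astype(float)
        m = np.log2((obs / lib[1]) / (ref / lib[0]))
        a = 0.5 * np.log2(obs / lib[1] * ref / lib[0])
        w = (lib[1] - obs) / (lib[1] * obs) + (lib[0] - ref) / (lib[0] * ref)
        n = len(m)
        lo_m, hi_m = np.floor(n * 0.3) + 1, n - np.floor(n * 0.3)
        lo_a, hi_a = np.floor(n * 0.05) + 1, n - np.floor(n * 0.05)
        rm, ra = sps.rankdata(m), sps.rankdata(a)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        expected = 2 ** (np.sum(m[keep] / w[keep]) / np.sum(1 / w[keep]))
        # geometric-mean normalization applies to both factors
        ratio_fast = f[1] / f[0]
        assert ratio_fast == pytest.approx(expected, rel=1e-10)
        # factors multiply library sizes, so the compositionally inflated
        # sample gets a factor below 1 (its effective size shrinks)
        assert f[1] < 1.0

    def test_all_zero_sample_is_error(self):
        with pytest.raises(ValueError, match="all-zero"):
            tmm_factors(_cm(np.column_stack([[1, 2], [0, 0]])))


class TestCpmFilter:
    def test_all_zero_counts_retain_nothing(self):
        cm = _cm(np.zeros((10, 3), dtype=int), lib_sizes=np.full(3, 1e6))
        assert cpm_filter(cm, 1.5, 1).sum() == 0

    def test_threshold_is_strict(self):
        cm = _cm(np.full((1, 2), 15), lib_sizes=np.full(2, 1e7))
        assert not cpm_filter(cm, 1.5, 1).any()  # CPM exactly 1.5, not > 1.5
        assert cpm_filter(cm, 1.4999, 1).all()

    def test_matches_brute_force(self, rng):
        counts = rng.poisson(3, (300, 5))
        lib = rng.uniform(5e5, 2e6, 5)
        cm = _cm(counts, lib_sizes=lib)
        mask = cpm_filter(cm, 1.0, 2)
        for g in range(300):
            n_over = sum(counts[g, s] / lib[s] * 1e6 > 1.0 for s in range(5))
            assert mask[g] == (n_over >= 2)


# ---------------------------------------------------------------------------
# NB GLM
# ---------------------------------------------------------------------------


class TestNBGLM:
    def test_one_group_closed_form(self):
        counts = np.array([[10, 10, 10, 10]])
        offs = np.full((1, 4), np.log(1e6))
        fit = fit_nb_glm(counts, np.ones((4, 1)), 0.1, offs)
        assert fit.coef[0, 0] == pytest.approx(np.log(10) - np.log(1e6), abs=1e-6)

    def test_two_group_saturated_logfc(self):
        counts = np.array([[10, 10, 40, 40]])
        X = np.column_stack([np.ones(4), [0, 0, 1, 1]])
        fit = fit_nb_glm(counts, X, 0.1, np.zeros((1, 4)))
        assert fit.coef[0, 1] == pytest.approx(np.log(4), abs=1e-6)

    def test_deviance_matches_loglik_oracle(self, rng):
        g, n = 50, 6
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n)])
        mu = rng.uniform(5, 200, (g, n))
        phi = 0.1
        r = 1 / phi
        counts = rng.negative_binomial(r, r / (r + mu))
        fit = fit_nb_glm(counts, X, phi, np.zeros((g, n)))

        def loglik(y, m):
            return sps.nbinom.logpmf(y, r, r / (r + np.maximum(m, 1e-8))).sum(axis=1)

        sat = loglik(counts, np.maximum(counts, 1e-8))
        dev_oracle = 2 * (sat - loglik(counts, fit.mu))
        np.testing.assert_allclose(fit.deviance, dev_oracle, atol=1e-6)


class TestDispersionTrend:
    def test_recovers_planted_dispersion(self, rng, nb_sampler):
        g, n, phi = 2000, 8, 0.05
        lib = np.full(n, 1e6)
        prop = rng.lognormal(-9, 1.5, g)
        prop /= prop.sum()
        counts = nb_sampler(rng, np.outer(prop, lib), phi)
        cm = _cm(counts, lib_sizes=lib)
        X = np.column_stack([np.ones(n), [0, 1] * 4])
        fit = estimate_dispersion_trend(cm, X)
        trend = fit(cm.ave_log_cpm())
        mid = (cm.ave_log_cpm() > np.quantile(cm.ave_log_cpm(), 0.2))
        assert np.median(trend[mid]) == pytest.approx(phi, rel=0.3)

    def test_poisson_data_gives_small_trend(self, rng):
        g, n = 2000, 8
        lib = np.full(n, 1e6)
        prop = rng.lognormal(-8, 1.0, g)
        prop /= prop.sum()
        counts = rng.poisson(np.outer(prop, lib))
        cm = _cm(counts, lib_sizes=lib)
        X = np.column_stack([np.ones(n), [0, 1] * 4])
        fit = estimate_dispersion_trend(cm, X)
        high = cm.ave_log_cpm() > np.quantile(cm.ave_log_cpm(), 0.5)
        assert np.median(fit(cm.ave_log_cpm())[high]) <= 0.02

    def test_deterministic(self, rng):
        counts = rng.poisson(20, (200, 4))
        cm = _cm(counts)
        X = np.column_stack([np.ones(4), [0, 1, 0, 1]])
        f1 = estimate_dispersion_trend(cm, X)
        f2 = estimate_dispersion_trend(cm, X)
        np.testing.assert_array_equal(f1.dispersion_grid, f2.dispersion_grid)


# ---------------------------------------------------------------------------
# QL test
# ---------------------------------------------------------------------------


def _null_cm(rng, g, n, phi, nb_sampler):
    lib = np.full(n, 1e6)
    prop = rng.lognormal(-9, 1.5, g)
    prop /= prop.sum()
    counts = nb_sampler(rng, np.outer(prop, lib), phi)
    return _cm(counts, lib_sizes=lib)


class TestQLTest:
    def test_null_calibration(self, nb_sampler):
        rng = np.random.default_rng(7)
        cm = _null_cm(rng, 5000, 8, 0.05, nb_sampler)
        X = np.column_stack([np.ones(8), [0, 1] * 4, [0, 0, 1, 1] * 2])
        tab = ql_test(cm, X, np.array([0.0, 1.0, 0.0]))
        frac = (tab["p"] < 0.05).mean()
        assert 0.035 <= frac <= 0.065

    def test_prior_zero_equals_deviance_f_oracle(self, rng, nb_sampler):
        cm = _null_cm(rng, 300, 6, 0.1, nb_sampler)
        X = np.column_stack([np.ones(6), [0, 1] * 3])
        cvec = np.array([0.0, 1.0])
        disp = estimate_dispersion_trend(cm, X)
        tab = ql_test(cm, X, cvec, dispfit=disp, prior_df=0)
        # oracle: plain F test from full/null deviances
        phi = disp(cm.ave_log_cpm())
        offs = cm.offset_matrix()
        full = fit_nb_glm(cm.counts, X, phi, offs)
        nullf = fit_nb_glm(cm.counts, X[:, :1], phi, offs)
        s2 = full.deviance / 4
        f_oracle = np.maximum(nullf.deviance - full.deviance, 0) / np.maximum(s2, 1e-10)
        p_oracle = sps.f.sf(f_oracle, 1, 4)
        np.testing.assert_allclose(tab["F"], f_oracle, rtol=1e-8, atol=1e-8)
        np.testing.assert_allclose(tab["p"], p_oracle, rtol=1e-8, atol=1e-10)

    def test_planted_effects_rank_above_null(self, nb_sampler):
        rng = np.random.default_rng(8)
        g, n = 2000, 8
        lib = np.full(n, 1e6)
        prop = rng.lognormal(-9, 1.0, g)
        prop /= prop.sum()
        logfc = np.zeros(g)
        logfc[:200] = 2.0
        cond = np.array([0, 1] * 4)
        mu = np.outer(prop, lib) * 2 ** np.outer(logfc, cond)
        cm = _cm(nb_sampler(rng, mu, 0.1), lib_sizes=lib)
        X = np.column_stack([np.ones(n), cond])
        tab = ql_test(cm, X, np.array([0.0, 1.0]))
        truth = logfc != 0
        auroc = sps.rankdata(-tab["p"])[truth].mean() / g
        # AUROC via rank-sum
        r = sps.rankdata(tab["p"])
        auroc = 1 - (r[truth].sum() - truth.sum() * (truth.sum() + 1) / 2) / (
            truth.sum() * (~truth).sum()
        )
        assert auroc >= 0.9

    def test_feature_order_invariance(self, rng, nb_sampler):
        cm = _null_cm(rng, 200, 6, 0.1, nb_sampler)
        X = np.column_stack([np.ones(6), [0, 1] * 3])
        cvec = np.array([0.0, 1.0])
        tab = ql_test(cm, X, cvec)
        perm = rng.permutation(200)
        cm2 = cm.subset(perm)
        tab2 = ql_test(cm2, X, cvec)
        np.testing.assert_allclose(
            tab["p"].to_numpy()[perm], tab2["p"].to_numpy(), rtol=1e-6, atol=1e-10
        )


class TestSqueeze:
    def test_squeezing_shrinks_toward_trend(self, rng):
        s2 = rng.chisquare(4, 500) / 4
        res = squeeze_variances(s2, 4, covariate=None, robust=True)
        assert (np.abs(res.var_post - res.var_prior) <= np.abs(s2 - res.var_prior) + 1e-12).all()

    def test_few_features_full_squeeze_with_warning(self):
        with pytest.warns(UserWarning, match="prior"):
            res = squeeze_variances(np.array([1.0, 2.0]), 4)
        assert np.isinf(res.df_prior)


# ---------------------------------------------------------------------------
# BH / Simes
# ---------------------------------------------------------------------------


class TestBH:
    def test_stepup_by_hand(self):
        adj = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.123]))[0] == pytest.approx(0.123)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]))

    @given(st_h.lists(st_h.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_definition(self, ps):
        p = np.array(ps)
        adj = bh_adjust(p)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        for i, idx in enumerate(order):
            expected = min(
                min(m * p[order[k]] / (k + 1) for k in range(i, m)), 1.0
            )
            assert adj[idx] == pytest.approx(expected, abs=1e-12)


def test_simes_by_hand():
    assert simes_p(np.array([0.001, 0.004])) == pytest.approx(0.002)
    assert simes_p(np.array([0.5])) == 0.5


# ---------------------------------------------------------------------------
# voom
# ---------------------------------------------------------------------------


class TestVoom:
    def test_prior_zero_equals_weighted_ls_oracle(self, rng, nb_sampler):
        cm = _null_cm(rng, 200, 6, 0.1, nb_sampler)
        X = np.column_stack([np.ones(6), [0, 1] * 3])
        cvec = np.array([0.0, 1.0])
        tab = voom_weighted_lm(cm, X, cvec, prior_df=0)
        # oracle: redo the WLS per feature with explicit linear algebra
        lib = cm.effective_lib_sizes
        y = np.log2((cm.counts + 0.5) / (lib + 1.0) * 1e6)
        # reproduce the voom weights from the first-pass trend
        from statsmodels.nonparametric.smoothers_lowess import lowess

        beta0 = y @ np.linalg.pinv(X).T
        resid = y - beta0 @ X.T
        sigma = np.sqrt((resid**2).sum(axis=1) / 4)
        sx = y.mean(axis=1) + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
        lo = lowess(np.sqrt(sigma), sx, frac=0.5, it=3)
        fitted_logcount = beta0 @ X.T + (np.log2(lib + 1.0) - np.log2(1e6))[None, :]
        w = np.maximum(np.interp(fitted_logcount, lo[:, 0], lo[:, 1]), 1e-6) ** -4
        for gidx in rng.choice(200, 20, replace=False):
            W = np.diag(w[gidx])
            A = X.T @ W @ X
            b = np.linalg.solve(A, X.T @ W @ y[gidx])
            rss = (w[gidx] * (y[gidx] - X @ b) ** 2).sum()
            s2 = rss / 4
            t_oracle = (cvec @ b) / np.sqrt(cvec @ np.linalg.solve(A, cvec) * s2)
            assert tab["t"].iloc[gidx] == pytest.approx(t_oracle, rel=1e-8)

    def test_equal_weights_logfc_is_group_mean_difference(self, rng):
        # identical abundances -> flat trend -> equal weights
        counts = rng.poisson(100, (50, 6))
        cm = _cm(counts, lib_sizes=np.full(6, 1e6))
        X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
        tab = voom_weighted_lm(cm, X, np.array([0.0, 1.0]))
        y = np.log2((counts + 0.5) / (1e6 + 1) * 1e6)
        expected = y[:, 3:].mean(axis=1) - y[:, :3].mean(axis=1)
        np.testing.assert_allclose(tab["logFC"], expected, atol=1e-6)

    def test_null_p_is_approximately_uniform(self, nb_sampler):
        rng = np.random.default_rng(11)
        cm = _null_cm(rng, 5000, 8, 0.05, nb_sampler)
        X = np.column_stack([np.ones(8), [0, 1] * 4, [0, 0, 1, 1] * 2])
        tab = voom_weighted_lm(cm, X, np.array([0.0, 1.0, 0.0]))
        assert sps.kstest(tab["p"], "uniform").statistic < 0.03


# ---------------------------------------------------------------------------
# distances and utility tests
# ---------------------------------------------------------------------------


class TestLeadingLogFC:
    def test_identical_samples_zero(self, rng):
        y = np.tile(rng.normal(size=100)[:, None], (1, 3))
        d = leading_logfc_distance(y, 20)
        np.testing.assert_allclose(d, 0.0)

    def test_constant_shift_on_top_n(self):
        y = np.zeros((100, 2))
        y[:30, 1] = 1.0
        assert leading_logfc_distance(y, 30)[0, 1] == pytest.approx(1.0)

    def test_matches_brute_force(self, rng):
        y = rng.normal(size=(200, 4))
        d = leading_logfc_distance(y, 50)
        for i in range(4):
            for j in range(4):
                diff2 = np.sort((y[:, i] - y[:, j]) ** 2)[-50:]
                assert d[i, j] == pytest.approx(np.sqrt(diff2.mean()))

    def test_batch_removal(self, rng):
        y = rng.normal(size=(300, 4))
        batch = np.array([0.0, 0.0, 1.0, 1.0])
        y_b = y + 5.0 * batch[None, :]
        d_corrected = leading_logfc_distance(y_b, 50, covariates=batch)
        d_uncorrected = leading_logfc_distance(y_b, 50)
        # correction subtracts a per-feature batch mean: within-batch
        # distances are untouched, the planted cross-batch shift disappears
        assert d_corrected[0, 1] == pytest.approx(d_uncorrected[0, 1], abs=1e-10)
        assert d_corrected[2, 3] == pytest.approx(d_uncorrected[2, 3], abs=1e-10)
        assert d_uncorrected[0, 2] > 5.0
        assert d_corrected[0, 2] < 3.0


def brute_force_fisher(table):
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    pmf = lambda x: sps.hypergeom.pmf(x, n, r1, c1)
    p_obs = pmf(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = pmf(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


class TestFisher:
    def test_crossed_table_by_hand(self):
        _, p = fisher_exact_2x2([[5, 0], [0, 5]])
        assert p == pytest.approx(2 / 252, rel=1e-9)

    def test_flat_table(self):
        _, p = fisher_exact_2x2([[1, 1], [1, 1]])
        assert p == 1.0

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [0, 2]])

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(100):
            t = rng.integers(0, 16, (2, 2))
            if t.sum() == 0:
                continue
            _, p = fisher_exact_2x2(t)
            assert p == pytest.approx(brute_force_fisher(t), rel=1e-7)


class TestWilcoxon:
    def test_identical_groups_not_significant(self):
        _, p = wilcoxon_rank_sum([1, 2, 3, 4], [1, 2, 3, 4])
        assert p > 0.5

    def test_extreme_separation_exact_p(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_small_samples_match_permutation_enumeration(self, rng):
        from itertools import combinations

        for _ in range(20):
            nx, ny = rng.integers(2, 5), rng.integers(2, 5)
            pooled = rng.permutation(np.arange(1.0, nx + ny + 1))  # no ties
            x, y = pooled[:nx], pooled[nx:]
            u_obs, p = wilcoxon_rank_sum(x, y)
            ranks = sps.rankdata(np.concatenate([x, y]))
            stat = lambda ix: ranks[list(ix)].sum()
            obs = stat(range(nx))
            n = nx + ny
            mean = nx * (n + 1) / 2
            count = sum(
                abs(stat(ix) - mean) >= abs(obs - mean) - 1e-9
                for ix in combinations(range(n), nx)
            )
            from math import comb

            assert p == pytest.approx(count / comb(n, nx), rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestMakeDesign:
    def test_columns_and_contrast(self, two_group_samples):
        X, cvec = make_design(two_group_samples, factors=("condition", "donor"))
        assert list(X.columns) == ["intercept", "condition[activated]", "donor[d2]"]
        np.testing.assert_array_equal(cvec, [0, 1, 0])

    def test_rank_deficiency_detected(self):
        samples = pd.DataFrame(
            {"sample": ["a", "b"], "condition": ["r", "a"], "donor": ["d1", "d2"]}
        )
        with pytest.raises(ValueError, match="rank"):
            make_design(samples, factors=("condition", "donor"))


class TestGlobalInvariances:
    def test_library_rescaling_invariance(self, rng, nb_sampler):
        cm = _null_cm(rng, 300, 6, 0.1, nb_sampler)
        X = np.column_stack([np.ones(6), [0, 1] * 3])
        cvec = np.array([0.0, 1.0])
        tab1 = ql_test(cm, X, cvec)
        cm2 = CountMatrix(cm.counts, list(cm.samples), lib_sizes=cm.lib_sizes * 10)
        tab2 = ql_test(cm2, X, cvec)
        np.testing.assert_allclose(tab1["logFC"], tab2["logFC"], atol=1e-4)
        np.testing.assert_allclose(tab1["p"], tab2["p"], rtol=1e-3, atol=1e-8)
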