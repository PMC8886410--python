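"""Repeated-median fitting against an independent brute-force oracle, the
fold-change algebra, fit statistics, and fdr-based sector assignment."""

import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from growthlaws import growthfit, synthetic
from growthlaws.fdr import fdr_from_pvalues, tail_fdr


def brute_repeated_median(mu, y):
    """Literal double-median enumeration, independent of the implementation."""
    n = len(mu)
    point_slopes, point_icpts = [], []
    for i in range(n):
        ss, tt = [], []
        for j in range(n):
            if j == i or abs(mu[j] - mu[i]) < 1e-12:
                continue
            ss.append((y[j] - y[i]) / (mu[j] - mu[i]))
            tt.append((mu[j] * y[i] - mu[i] * y[j]) / (mu[j] - mu[i]))
        point_slopes.append(statistics.median(ss))
        point_icpts.append(statistics.median(tt))
    return statistics.median(point_slopes), statistics.median(point_icpts)


class TestRmlmFit:
    def test_exact_line(self):
        a, b = growthfit.rmlm_fit([0, 1, 2], [1, 2, 3])
        assert (a, b) == (1.0, 1.0)

    def test_single_gross_outlier_ignored(self):
        # per-point slope medians are (1, 1, 1, 1, 41); overall median 1
        a, b = growthfit.rmlm_fit([0, 1, 2, 3, 4], [0, 1, 2, 3, 100])
        assert (a, b) == (1.0, 0.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            n = rng.integers(3, 13)
            mu = rng.uniform(0, 0.3, n)
            y = rng.normal(0, 5, n)
            a, b = growthfit.rmlm_fit(mu, y)
            a0, b0 = brute_repeated_median(mu.tolist(), y.tolist())
            assert a == pytest.approx(a0, abs=1e-12)
            assert b == pytest.approx(b0, abs=1e-12)

    def test_robust_to_forty_percent_outliers(self):
        mu = np.repeat(np.linspace(0.05, 0.28, 8), 3)
        y = mu + 0.1
        y[-9:] += 5.0  # 9/24 points grossly induced in the top conditions
        a, _ = growthfit.rmlm_fit(mu, y)
        assert a == pytest.approx(1.0, rel=0.05)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            growthfit.rmlm_fit([0.1, 0.2], [1, 2])
        with pytest.raises(ValueError):
            growthfit.rmlm_fit([0.1, 0.1, 0.1], [1, 2, 3])

    def test_matrix_path_handles_missing_values(self):
        mu = np.linspace(0.05, 0.3, 6)
        y = np.vstack([2 * mu + 1, 2 * mu + 1])
        y[1, [0, 3]] = np.nan
        slope, icpt = growthfit.rmlm_fit_matrix(mu, y)
        np.testing.assert_allclose(slope, 2.0, atol=1e-12)
        np.testing.assert_allclose(icpt, 1.0, atol=1e-12)


class TestFoldChange:
    def test_hand_examples(self):
        assert growthfit.fold_change(1.0, 0.0, 0.3) == 2.0
        assert growthfit.fold_change(0.0, 5.0) == 0.0
        assert growthfit.fold_change(-1.0, 0.3, 0.3) == -2.0

    def test_zero_midpoint_flagged_missing(self):
        assert np.isnan(growthfit.fold_change(1.0, -0.15, 0.3))

    def test_definition_matches_line_evaluation(self):
        # FC = (y(mu_max) - y(0)) / y(mu_max/2) for the fitted line
        rng = np.random.default_rng(5)
        a = rng.normal(0, 3, 1000)
        b = rng.normal(2, 3, 1000)
        mid = a * 0.15 + b
        ok = (np.abs(mid) > 1e-6) & (a != 0)
        direct = (a * 0.3 + b - b) / mid
        np.testing.assert_allclose(
            growthfit.fold_change(a, b)[ok], direct[ok], atol=1e-12
        )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(c=st.floats(1e-3, 1e3), a=st.floats(-5, 5), b=st.floats(0.1, 5))
    def test_scale_invariance(self, c, a, b):
        fc1 = growthfit.fold_change(a, b)
        fc2 = growthfit.fold_change(c * a, c * b)
        assert fc2 == pytest.approx(fc1, rel=1e-9)


class TestFitStatistics:
    def test_perfect_line(self):
        mu = np.linspace(0.05, 0.3, 8)
        y = 2 * mu + 1
        r2, ssr, p = growthfit.fit_statistics(mu, y, 2.0, 1.0)
        assert r2 == pytest.approx(1.0)
        assert ssr == pytest.approx(0.0, abs=1e-15)
        assert p < 1e-12

    def test_flat_noise_gives_null_p(self):
        rng = np.random.default_rng(8)
        mu = np.linspace(0.05, 0.3, 24)
        y = rng.normal(5, 1, 24)
        a, b = growthfit.rmlm_fit(mu, y)
        r2, _, p = growthfit.fit_statistics(mu, y, a, b)
        assert r2 < 0.3
        assert p > 0.05

    def test_p_matches_t_tail_closed_form(self):
        # the reported p must equal the two-sided t_{N-2} tail at
        # sqrt(R^2/(1-R^2) (N-2)), an independent route to the F(1, N-2) tail
        from scipy import stats

        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(5, 30))
            mu = np.linspace(0.05, 0.3, n)
            y = rng.normal(0, 1, n) + rng.uniform(-3, 3) * mu
            a, b = growthfit.rmlm_fit(mu, y)
            r2, _, p = growthfit.fit_statistics(mu, y, a, b)
            if r2 <= 0:
                assert p == 1.0
                continue
            t_stat = np.sqrt(r2 / (1 - r2) * (n - 2))
            assert p == pytest.approx(2 * stats.t.sf(t_stat, n - 2), rel=1e-9)

    def test_ssr_normalisation_scale(self):
        # SSR_norm = sum(r^2) / ((N-1) * mean(y))
        mu = np.array([0.1, 0.2, 0.3])
        y = np.array([1.0, 2.0, 4.0])
        a, b = growthfit.rmlm_fit(mu, y)
        resid = y - (a * mu + b)
        _, ssr, _ = growthfit.fit_statistics(mu, y, a, b)
        assert ssr == pytest.approx(np.sum(resid**2) / (2 * y.mean()))


class TestFdrAssign:
    def test_pure_null_assigns_almost_everything_q(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=2000)
        slopes = rng.normal(size=2000)
        out = growthfit.fdr_assign(p, slopes)
        assert (out["sector"] != "Q").mean() <= 0.15

    def test_zero_p_assigned_by_slope_sign(self):
        p = np.concatenate([[0.0, 0.0], np.random.default_rng(1).uniform(size=100)])
        slopes = np.concatenate([[1.0, -1.0], np.zeros(100)])
        out = growthfit.fdr_assign(p, slopes)
        assert out.loc[0, "q"] == 0.0
        assert out.loc[0, "sector"] == "R"
        assert out.loc[1, "sector"] == "P"

    def test_forced_eta0_reduces_to_bh(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(size=300) ** 2
        q = tail_fdr(p, eta0=1.0)
        _, bh, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, bh, atol=1e-12)

    def test_small_input_falls_back_to_bh_with_warning(self):
        p = np.linspace(0.01, 0.9, 10)
        with pytest.warns(UserWarning, match="Benjamini"):
            res = fdr_from_pvalues(p)
        assert res.method == "bh-fallback"


class TestFitAllGenes:
    def test_noiseless_recovery_to_1e9(self, design):
        truth = synthetic.generate_gene_parameters(
            150, condition_effect_fraction=0.0, seed=20
        )
        levels = synthetic.latent_levels(truth, design)
        fits = growthfit.fit_all_genes(levels, design)
        np.testing.assert_allclose(
            fits["slope"].to_numpy(), truth["slope_true"].to_numpy(), atol=1e-9
        )
        np.testing.assert_allclose(
            fits["intercept"].to_numpy(), truth["intercept_true"].to_numpy(), atol=1e-9
        )
        assert len(fits) == len(truth)

    def test_constant_gene_is_q(self, design):
        df = pd.DataFrame(
            np.vstack([np.full(24, 7.0)] + [np.random.default_rng(3).uniform(1, 2, 24) for _ in range(60)]),
            columns=design["sample_id"],
        )
        fits = growthfit.fit_all_genes(df, design)
        assert fits.iloc[0]["sector"] == "Q"
        assert fits.iloc[0]["slope"] == 0.0


class TestSetsumAndRatio:
    def test_full_set_of_fractions_sums_to_one(self, small_matrix):
        frac = small_matrix / small_matrix.sum(axis=0)
        profile, report = growthfit.setsum_profile(frac, list(small_matrix.index))
        np.testing.assert_allclose(profile, 1.0, atol=1e-12)
        assert report["n_missing"] == 0

    def test_disjoint_sets_add(self, small_matrix):
        p1, _ = growthfit.setsum_profile(small_matrix, ["g0", "g1"])
        p2, _ = growthfit.setsum_profile(small_matrix, ["g2"])
        p12, _ = growthfit.setsum_profile(small_matrix, ["g0", "g1", "g2"])
        np.testing.assert_allclose(p1 + p2, p12)

    def test_empty_intersection_errors(self, small_matrix):
        with pytest.raises(ValueError, match="no members"):
            growthfit.setsum_profile(small_matrix, ["nope"])

    def test_ratio_trend_identity_and_monotonicity(self):
        grid = np.linspace(0, 0.3, 101)
        out = growthfit.ratio_trend((2.0, 1.0), (2.0, 1.0), grid)
        np.testing.assert_allclose(out["ratio"], 1.0)
        assert not out["flagged"].any()
        # FC_A > FC_B > 0 implies an increasing ratio of lines
        a_fit = (2.0, 0.1)  # FC ~ 1.5
        b_fit = (1.0, 0.4)  # FC ~ 0.55
        out = growthfit.ratio_trend(a_fit, b_fit, grid)
        assert (np.diff(out["ratio"]) > 0).all()

    def test_ratio_trend_flags_zero_crossing(self):
        grid = np.linspace(0, 0.3, 31)
        out = growthfit.ratio_trend((1.0, 1.0), (1.0, -0.15), grid)
        assert out["flagged"].any()


class TestBootstrap:
    def test_zero_noise_band_collapses(self):
        mu = np.repeat(np.linspace(0.05, 0.28, 8), 3)
        y = 3 * mu + 0.5
        band = growthfit.bootstrap_growth_law(mu, y, n_boot=200, seed=0)
        assert np.max(band.upper - band.lower) < 1e-9
        np.testing.assert_allclose(band.predicted, 3 * band.grid + 0.5)
        assert band.fc_sd < 1e-9

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(31)
        mu = np.repeat(np.linspace(0.05, 0.28, 8), 3)
        y = 2 * mu + 0.3 + rng.normal(0, 0.1, mu.size)
        b1 = growthfit.bootstrap_growth_law(mu, y, n_boot=100, seed=5)
        b2 = growthfit.bootstrap_growth_law(mu, y, n_boot=100, seed=5)
        np.testing.assert_array_equal(b1.lower, b2.lower)
        assert b1.fc_mean == b2.fc_mean

    def test_needs_four_points(self):
        with pytest.raises(ValueError):
            growthfit.bootstrap_growth_law([0.1, 0.2, 0.3], [1, 2, 3])
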