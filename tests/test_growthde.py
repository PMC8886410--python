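"""ANOVA screening, growth-trend normalization arithmetic, the synthetic
reference, and calibration of the NB Wald test (with a statsmodels GLM as
the independent oracle for the likelihood machinery)."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from growthlaws import growthde, growthfit, quantify, synthetic


def holm_by_hand(p):
    """Step-down Holm adjustment, literal definition."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(running, 1.0)
    return adj


@pytest.fixture(scope="module")
def de_setup():
    """Counts with pure-growth, condition-effect, and null genes, fitted and
    normalized once for the module."""
    design = synthetic.generate_design(seed=5)
    truth = synthetic.generate_gene_parameters(
        400, sector_props=(0.2, 0.1, 0.7), condition_effect_fraction=0.0, seed=6
    )
    effect_genes = truth.index[truth["sector_true"] == "Q"][:80]
    truth.loc[effect_genes, "cond_fx_04"] = 1.0
    truth["dispersion"] = 0.05
    counts = synthetic.simulate_rna_counts(
        truth, design, mean_depth=500 * len(truth), seed=7
    )
    sf = quantify.size_factors(counts)
    norm = quantify.normalize_counts(counts, sf)
    fits = growthfit.fit_all_genes(norm, design)
    gn = growthde.growth_normalization_factors(counts, sf, fits, design)
    return design, truth, effect_genes, counts, sf, fits, gn


class TestAnovaScreen:
    def make_design(self):
        return synthetic.generate_design(n_conditions=4, seed=2)

    def test_planted_condition_effects_flagged(self):
        design = self.make_design()
        rng = np.random.default_rng(0)
        base = rng.normal(10, 0.2, size=(30, len(design)))
        shift = design["condition"].eq("C02").to_numpy() * 5.0
        base[:10] += shift
        df = pd.DataFrame(base, columns=design["sample_id"])
        out = growthde.anova_variability_screen(df, design)
        assert out["variable"].iloc[:10].all()
        assert not out["variable"].iloc[10:].any()

    def test_p_matches_scipy_f_oneway(self):
        design = self.make_design()
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(5, len(design))), columns=design["sample_id"])
        out = growthde.anova_variability_screen(df, design)
        cond = design.set_index("sample_id")["condition"]
        for gene, row in df.iterrows():
            groups = [row[cond[cond == c].index].to_numpy() for c in cond.unique()]
            assert out.loc[gene, "p"] == pytest.approx(
                stats.f_oneway(*groups).pvalue, rel=1e-9
            )

    def test_holm_adjustment_matches_step_down_by_hand(self):
        design = self.make_design()
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(40, len(design))), columns=design["sample_id"])
        out = growthde.anova_variability_screen(df, design)
        np.testing.assert_allclose(
            out["p_holm"], holm_by_hand(out["p"].to_numpy()), atol=1e-12
        )
        # the printed toy example: Holm on (0.01, 0.04) -> (0.02, 0.04)
        np.testing.assert_allclose(holm_by_hand(np.array([0.01, 0.04])), [0.02, 0.04])

    def test_null_simulation_rarely_flags(self):
        design = self.make_design()
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            rng.normal(size=(2000, len(design))), columns=design["sample_id"]
        )
        out = growthde.anova_variability_screen(df, design)
        # Holm controls the family-wise error at 5%
        assert out["variable"].sum() <= 1


class TestGrowthNormalization:
    def test_perfect_fit_gene_has_unit_factors(self, de_setup):
        design, *_ = de_setup
        mu = design["growth_rate"].to_numpy()
        counts = pd.DataFrame(
            np.rint(100 * (2 * mu + 1))[None, :].repeat(60, axis=0)
            + np.arange(60)[:, None],  # distinct rows, all near-linear
            columns=design["sample_id"],
        ).astype(int)
        sf = pd.Series(1.0, index=counts.columns)
        fits = growthfit.fit_all_genes(counts, design)
        gn = growthde.growth_normalization_factors(counts, sf, fits, design)
        # well-fitted linear genes: factors deviate from 1 only by rounding
        np.testing.assert_allclose(gn.factors.to_numpy(), 1.0, atol=0.01)

    def test_flat_gene_with_doubled_observation(self):
        design = synthetic.generate_design(n_conditions=4, seed=3)
        n = len(design)
        row = np.full(n, 100.0)
        row[0] = 200.0
        counts = pd.DataFrame(
            np.vstack([row, np.full(n, 50.0)]), columns=design["sample_id"]
        ).astype(int)
        sf = pd.Series(1.0, index=counts.columns)
        fits = growthfit.fit_all_genes(counts, design)
        gn = growthde.growth_normalization_factors(counts, sf, fits, design)
        g = np.exp(np.mean(np.log(row / 100.0)))  # geometric mean of raw ratios
        np.testing.assert_allclose(gn.factors.iloc[0, 0], 2.0 / g, rtol=1e-9)
        np.testing.assert_allclose(gn.factors.iloc[0, 1:], 1.0 / g, rtol=1e-9)

    def test_factors_have_unit_geometric_mean(self, de_setup):
        # zeros propagate as zero factors and stay outside the rescale, so
        # the unit-product invariant holds over the positive entries
        *_, gn = de_setup
        f = gn.factors.to_numpy()
        logf = np.where(f > 0, np.log(np.where(f > 0, f, 1.0)), np.nan)
        np.testing.assert_allclose(np.exp(np.nanmean(logf, axis=1)), 1.0, atol=1e-9)

    def test_negative_prediction_excluded_and_listed(self):
        design = synthetic.generate_design(seed=4)
        mu = design["growth_rate"].to_numpy()
        good = np.rint(100 * (2 * mu + 1))
        steep = np.rint(np.maximum(1000 * (0.1 - mu), 0))  # negative beyond mu=0.1
        counts = pd.DataFrame(
            np.vstack([good, steep]), columns=design["sample_id"], index=["ok", "neg"]
        ).astype(int)
        sf = pd.Series(1.0, index=counts.columns)
        fits = growthfit.fit_all_genes(counts, design)
        gn = growthde.growth_normalization_factors(counts, sf, fits, design)
        assert "neg" in gn.excluded
        assert "ok" in gn.pred_raw.index


class TestSyntheticReference:
    def test_constant_predictions_round_trip(self, de_setup):
        design, *_ = de_setup
        # flat gene: q constant across conditions -> s = round(q)
        counts = pd.DataFrame(
            np.vstack([np.full(24, 100), np.full(24, 51)]),
            columns=design["sample_id"],
        ).astype(int)
        sf = pd.Series(1.0, index=counts.columns)
        fits = growthfit.fit_all_genes(counts, design)
        gn = growthde.growth_normalization_factors(counts, sf, fits, design)
        ref_counts, ref_expo = growthde.synthetic_reference(gn)
        assert ref_counts.shape[1] == 3
        np.testing.assert_allclose(ref_counts.iloc[0], 100)
        assert ref_counts.dtypes.eq(np.int64).all()

    def test_median_then_round(self):
        # median of (10.2, 10.6, 30.0) is 10.6, rounded to 11
        design = synthetic.generate_design(n_conditions=3, n_replicates=1, seed=1)
        gn = growthde.GrowthNormalization(
            pred_normalized=pd.DataFrame(),
            pred_raw=pd.DataFrame(
                [[10.2, 10.6, 30.0]], index=["g0"], columns=design["sample_id"]
            ),
            factors=pd.DataFrame(),
            size_factors=pd.Series(dtype=float),
            excluded=[],
            design=design,
        )
        ref_counts, _ = growthde.synthetic_reference(gn)
        assert ref_counts.iloc[0, 0] == 11


class TestNbDeTest:
    def test_lfc_matches_statsmodels_glm(self, de_setup):
        # dual route: the per-group Fisher-scoring MLE must agree with a
        # statsmodels NB GLM at the same fixed dispersion
        import statsmodels.api as sm

        design, truth, effect_genes, counts, sf, fits, gn = de_setup
        # full-fit exposures so the oracle design matrix matches exactly
        table = growthde.nb_de_test(counts, gn, loco=False)
        ref_counts, ref_expo = growthde.synthetic_reference(gn)
        meta = design.set_index("sample_id")
        for gene in gn.pred_raw.index[:5]:
            row = table[(table["gene_id"] == gene) & (table["condition"] == "C04")].iloc[0]
            cols = [c for c in gn.pred_raw.columns if meta.loc[c, "condition"] == "C04"]
            y = np.concatenate(
                [counts.loc[gene, cols].to_numpy(), ref_counts.loc[gene].to_numpy()]
            )
            e = np.concatenate(
                [gn.pred_raw.loc[gene, cols].to_numpy(), ref_expo.loc[gene].to_numpy()]
            )
            x = np.column_stack([np.ones(6), [1, 1, 1, 0, 0, 0]])
            glm = sm.GLM(
                y,
                x,
                family=sm.families.NegativeBinomial(alpha=row["dispersion"]),
                offset=np.log(e),
            ).fit()
            assert row["lfc_raw"] == pytest.approx(glm.params[1] / np.log(2), abs=1e-4)

    def test_pure_growth_genes_not_called(self, de_setup):
        design, truth, effect_genes, counts, sf, fits, gn = de_setup
        table = growthde.nb_de_test(counts, gn)
        table, union, _ = growthde.call_de(table)
        growth = [g for g in truth.index[truth["sector_true"] != "Q"] if g in union.index]
        assert union.loc[growth].mean() < 0.02

    def test_planted_condition_effect_detected(self, de_setup):
        design, truth, effect_genes, counts, sf, fits, gn = de_setup
        table = growthde.nb_de_test(counts, gn)
        table, union, signature = growthde.call_de(table)
        hits = [g for g in effect_genes if g in union.index]
        assert union.loc[hits].mean() >= 0.7
        # the raw fold change recovers the planted log2 effect; the shrunk
        # one is pulled toward zero but stays callable
        sub = table[(table["gene_id"].isin(hits)) & (table["condition"] == "C04")]
        assert sub["lfc_raw"].median() == pytest.approx(1.0, abs=0.2)
        assert (sub["lfc_shrunk"].abs() <= sub["lfc_raw"].abs() + 1e-12).all()
        assert sub["lfc_shrunk"].median() > 0.5
        # no effect leaks into the other conditions
        other = table[(table["gene_id"].isin(hits)) & (table["condition"] == "C03")]
        assert abs(other["lfc_raw"].median()) < 0.15

    def test_null_pvalues_roughly_uniform(self, de_setup):
        design, truth, effect_genes, counts, sf, fits, gn = de_setup
        table = growthde.nb_de_test(counts, gn)
        null_genes = truth.index[truth["sector_true"] == "Q"][80:]
        sub = table[table["gene_id"].isin(null_genes) & (table["condition"] != "C04")]
        p = sub["p"].to_numpy()
        # no gross anti-conservative spike near zero
        assert (p < 0.01).mean() < 0.03
        assert 0.3 < (p < 0.5).mean() < 0.7

    def test_trend_removal_on_corrected_counts(self, de_setup):
        design, truth, effect_genes, counts, sf, fits, gn = de_setup
        corr = growthde.corrected_counts(counts, gn)
        mu = design["growth_rate"].to_numpy()
        slope, _ = growthfit.rmlm_fit_matrix(mu, corr.to_numpy())
        rel = np.abs(slope) * 0.3 / np.nanmedian(corr.to_numpy(), axis=1)
        well_fit = (fits.loc[corr.index, "r2"] > 0.5).to_numpy()
        assert np.nanmedian(rel[well_fit]) < 0.05


class TestShrinkAndCall:
    def make_table(self):
        return pd.DataFrame(
            {
                "gene_id": ["a", "b", "c"],
                "condition": ["C1"] * 3,
                "lfc_raw": [2.0, 2.0, 0.1],
                "se": [0.1, 1.5, 0.1],
                "p": [1e-6, 0.2, 0.5],
                "p_adj": [3e-6, 0.3, 0.5],
            }
        )

    def test_prior_limits(self):
        t = self.make_table()
        np.testing.assert_allclose(
            growthde.shrink_lfc(t, prior_scale=1e6), t["lfc_raw"], rtol=1e-5
        )
        # scale -> 0: noisy entries collapse to zero, but a decisively
        # determined signal survives (the heavy-tailed prior's spike cannot
        # outweigh a likelihood concentrated far from zero)
        tiny = growthde.shrink_lfc(t, prior_scale=1e-8)
        np.testing.assert_allclose(tiny[1:], 0.0, atol=1e-5)
        assert tiny[0] == pytest.approx(t["lfc_raw"][0], abs=0.05)

    def test_high_precision_genes_shrink_less(self):
        t = self.make_table()
        shrunk = growthde.shrink_lfc(t)
        assert abs(shrunk[0]) > abs(shrunk[1])  # same raw LFC, smaller SE
        assert (np.abs(shrunk) <= np.abs(t["lfc_raw"]) + 1e-12).all()

    def test_strict_thresholds_and_union(self):
        t = self.make_table()
        t["lfc_shrunk"] = t["lfc_raw"]
        t.loc[1, "p_adj"] = 0.01  # exactly at the threshold: not DE
        t.loc[1, "lfc_shrunk"] = 2.0
        out, union, _ = growthde.call_de(t)
        assert out["de"].tolist() == [True, False, False]
        assert union.loc["a"] and not union.loc["b"]
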