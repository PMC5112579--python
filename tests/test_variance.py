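"""Mean-variance trend, variance decomposition, HVG selection, covariates."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from scworkflow import (
    decompose_variance,
    design_matrix,
    explained_variance,
    fit_trend,
    gene_stats,
    remove_nuisance,
    select_hvgs,
)


class TestGeneStats:
    def test_constant_gene_zero_variance(self):
        Y = np.vstack([np.full(10, 3.0), np.arange(10.0)])
        out = gene_stats(Y)
        assert out["total"][0] == 0.0
        assert out["df"][0] == 9

    def test_two_group_design_equals_pooled_within_variance(self, rng):
        group = np.repeat([0, 1], 15)
        y = rng.normal(size=30) + 2.0 * group
        X = design_matrix(group.astype(str))
        out = gene_stats(y[None, :], design=X)
        a, b = y[group == 0], y[group == 1]
        pooled = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (30 - 2)
        assert out["total"][0] == pytest.approx(pooled, rel=1e-12)
        assert out["df"][0] == 28

    def test_no_design_equals_intercept_only(self, rng):
        Y = rng.normal(size=(5, 12))
        plain = gene_stats(Y)
        inter = gene_stats(Y, design=np.ones((12, 1)))
        np.testing.assert_allclose(plain["total"], inter["total"])
        assert (plain["df"] == inter["df"]).all()

    def test_rank_deficient_design_rejected(self, rng):
        X = np.ones((10, 2))
        with pytest.raises(ValueError, match="rank"):
            gene_stats(rng.normal(size=(3, 10)), design=X)


class TestTrend:
    def test_reproduces_linear_function(self, rng):
        x = np.sort(rng.uniform(0, 10, 200))
        y = 2.0 + 0.5 * x
        for span in (0.2, 0.5, 1.0):
            trend = fit_trend(x, y, span=span)
            grid = np.linspace(x.min(), x.max(), 50)
            np.testing.assert_allclose(trend(grid), 2.0 + 0.5 * grid, atol=1e-8)

    def test_constant_variances_give_constant_trend(self, rng):
        x = rng.uniform(0, 5, 50)
        trend = fit_trend(x, np.full(50, 4.0), span=0.3)
        np.testing.assert_allclose(trend(np.linspace(-1, 6, 10)), 4.0, atol=1e-10)

    def test_constant_extrapolation_outside_range(self, rng):
        x = np.linspace(1, 2, 30)
        trend = fit_trend(x, 3 * x, span=0.5)
        assert trend(0.0) == pytest.approx(trend(1.0))
        assert trend(10.0) == pytest.approx(trend(2.0))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_trend(np.arange(5), np.arange(5), span=0.5)

    def test_fitted_values_clamped_nonnegative(self):
        x = np.linspace(0, 1, 20)
        y = np.linspace(1, -1, 20)  # linear trend crossing zero
        trend = fit_trend(x, y, span=1.0)
        assert (trend(x) >= 0).all()


class TestDecompose:
    def _stats(self, total, df=50, mean=5.0):
        return pd.DataFrame({"mean": [mean], "total": [total], "df": [df]})

    def _flat_trend(self, level):
        x = np.linspace(0, 10, 20)
        return fit_trend(x, np.full(20, float(level)), span=1.0)

    def test_bio_is_total_minus_tech(self):
        out = decompose_variance(self._stats(10.0), self._flat_trend(7.0))
        assert out["bio"][0] == pytest.approx(3.0)
        assert out["bio"][0] + out["tech"][0] == out["total"][0]

    def test_chi_square_tail_oracle(self):
        # total == tech with df 50: p is the upper chi2_50 tail at 50
        out = decompose_variance(self._stats(7.0, df=50), self._flat_trend(7.0))
        assert out["p.value"][0] == pytest.approx(sps.chi2.sf(50, 50), rel=1e-12)
        assert out["p.value"][0] == pytest.approx(0.4734, abs=5e-4)

    def test_nonpositive_tech_gives_missing_p(self):
        with pytest.warns(UserWarning, match="non-positive"):
            out = decompose_variance(self._stats(5.0), self._flat_trend(0.0))
        assert np.isnan(out["p.value"][0])

    def test_exact_additivity_many_genes(self, rng):
        means = rng.uniform(0, 8, 300)
        totals = rng.uniform(0.1, 5, 300)
        stats_table = pd.DataFrame({"mean": means, "total": totals, "df": 40})
        trend = fit_trend(means, totals, span=0.3)
        out = decompose_variance(stats_table, trend)
        np.testing.assert_allclose(out["bio"] + out["tech"], out["total"], rtol=1e-13)
        ok = out["FDR"].notna()
        assert (out.loc[ok, "FDR"] >= out.loc[ok, "p.value"] - 1e-15).all()


class TestSelectHvgs:
    def test_rule_application(self):
        table = pd.DataFrame(
            {"FDR": [0.01, 0.01, 0.10], "bio": [0.6, 0.4, 0.9], "mean": 0, "total": 1, "tech": 1}
        )
        out = select_hvgs(table)
        assert list(out.index) == [0]

    def test_sorted_by_bio_descending(self):
        table = pd.DataFrame({"FDR": [0.01] * 3, "bio": [0.7, 2.0, 1.1]})
        assert list(select_hvgs(table)["bio"]) == [2.0, 1.1, 0.7]

    def test_monotone_in_thresholds(self, rng):
        table = pd.DataFrame({"FDR": rng.uniform(0, 0.2, 100), "bio": rng.uniform(0, 2, 100)})
        base = set(select_hvgs(table, fdr=0.05, bio_min=0.5).index)
        assert set(select_hvgs(table, fdr=0.01, bio_min=0.5).index) <= base
        assert set(select_hvgs(table, fdr=0.05, bio_min=1.0).index) <= base


class TestExplainedVariance:
    def test_gene_equal_to_factor_is_100(self, rng):
        f = rng.normal(size=50)
        out = explained_variance(f[None, :], f)
        assert out[0] == pytest.approx(100.0)

    def test_independent_gene_near_zero(self, rng):
        Y = rng.normal(size=(200, 1000))
        f = rng.normal(size=1000)
        out = explained_variance(Y, f)
        assert out.mean() < 1.0
        assert ((out >= 0) & (out <= 100)).all()

    def test_categorical_factor_accepted(self, rng):
        f = np.array(["a", "b"] * 25)
        y = (f == "b").astype(float) * 2 + rng.normal(0, 0.01, 50)
        assert explained_variance(y[None, :], f)[0] > 99

    def test_constant_factor_rejected(self, rng):
        with pytest.raises(ValueError):
            explained_variance(rng.normal(size=(2, 10)), np.ones(10))


class TestRemoveNuisance:
    def test_identity_without_terms(self, rng):
        Y = rng.normal(size=(4, 20))
        np.testing.assert_array_equal(remove_nuisance(Y), Y)

    def test_batch_shift_removed_round_trip(self, rng):
        batch = np.repeat(["x", "y"], 30)
        Y = rng.normal(size=(50, 60))
        Y[:, batch == "y"] += 3.0
        corrected = remove_nuisance(Y, batch=batch)
        assert explained_variance(corrected, batch).mean() < 1e-10
        # grand means preserved by the centred contrasts
        np.testing.assert_allclose(corrected.mean(axis=1), Y.mean(axis=1), atol=1e-10)

    def test_two_batch_group_means_equalized(self):
        batch = np.repeat(["a", "b"], 10)
        y = np.where(batch == "b", 5.0, 1.0)[None, :]
        corrected = remove_nuisance(y, batch=batch)
        assert corrected[0, :10].mean() == pytest.approx(corrected[0, 10:].mean())

    def test_confounded_design_rejected(self):
        batch = np.repeat(["a", "b"], 5)
        cov = (batch == "b").astype(float)
        with pytest.raises(ValueError, match="confounded"):
            remove_nuisance(np.ones((2, 10)), batch=batch, covariates=cov)


class TestTrendSources:
    def test_spike_and_endogenous_trends_agree_when_purely_technical(self, rng):
        """When endogenous genes carry no biology, both fits see one curve."""
        means_endo = rng.uniform(1, 8, 2000)
        means_spike = rng.uniform(1, 8, 60)
        curve = lambda m: 4.0 / (1 + np.exp(m - 4))  # decreasing noise curve
        n = 80
        var_endo = curve(means_endo) * sps.chi2.rvs(n - 1, size=2000, random_state=1) / (n - 1)
        var_spike = curve(means_spike) * sps.chi2.rvs(n - 1, size=60, random_state=2) / (n - 1)
        t_endo = fit_trend(means_endo, var_endo, span=0.2, source="endogenous")
        t_spike = fit_trend(means_spike, var_spike, span=0.6, source="spikes")
        grid = np.linspace(2, 7, 25)
        rel = np.abs(t_spike(grid) - t_endo(grid)) / t_endo(grid)
        assert np.median(rel) < 0.10

    def test_blocked_decomposition_null_uniform(self, rng):
        """With blocking on a planted factor, non-DE gene p-values stay uniform."""
        n, g = 60, 600
        batch = np.repeat(["m", "f"], n // 2)
        Y = rng.normal(0, 1, size=(g, n)) + 5.0
        Y[:, batch == "f"] += rng.normal(0, 1, size=(g, 1))  # per-gene batch shift
        X = design_matrix(batch)
        stats_table = gene_stats(Y, design=X)
        trend = fit_trend(stats_table["mean"], stats_table["total"], span=0.4)
        out = decompose_variance(stats_table, trend)
        p = out["p.value"].dropna()
        assert sps.kstest(p, "uniform").pvalue > 0.01
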