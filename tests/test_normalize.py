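"""Size-factor estimation (deconvolution, spike-in) and log-normalization."""

import subprocess

import numpy as np
import pytest

from scworkflow import (
    build_experiment,
    compute_spike_factors,
    compute_sum_factors,
    deconvolve_size_factors,
    normalize_log,
    quick_cluster,
    simulate_counts,
)


def no_de_counts(rng, n_genes=80, n_cells=100, lo=0.25, hi=4.0):
    """Continuous no-DE matrix counts[g,c] = mu_g * t_c (analytic case)."""
    mu = rng.lognormal(3, 1, n_genes)
    t = np.linspace(lo, hi, n_cells)
    return mu[:, None] * t[None, :], t


class TestDeconvolution:
    def test_no_de_analytic_exactness(self, rng):
        counts, t = no_de_counts(rng)
        factors = compute_sum_factors(counts)
        truth = t / t.mean()
        np.testing.assert_allclose(factors, truth, rtol=1e-6)

    def test_identical_cells_give_unit_factors(self):
        counts = np.tile(np.arange(1, 31)[:, None], (1, 50))
        np.testing.assert_allclose(compute_sum_factors(counts), np.ones(50), rtol=1e-9)

    def test_centred_to_mean_one(self, rng):
        exp, _ = simulate_counts(n_genes=80, n_cells=60, n_spikes=0, mean_log2=5, seed=3)
        factors = compute_sum_factors(exp.counts, sizes=[10, 20, 30])
        assert factors.mean() == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance_per_cell(self, rng):
        """Multiplying one cell's counts by k multiplies its factor by k."""
        counts, _ = no_de_counts(rng, n_cells=60)
        base = compute_sum_factors(counts)
        scaled = counts.copy()
        scaled[:, 7] *= 3.0
        new = compute_sum_factors(scaled)
        ratio = new[7] / base[7]
        others = np.delete(new / base, 7)
        # renormalization shifts everything by the same constant
        assert ratio / others.mean() == pytest.approx(3.0, rel=1e-6)

    def test_collinear_with_library_size_without_de(self):
        # no DE and no gene-level overdispersion: library size is purely
        # depth-driven and the factors should track it tightly
        exp, _ = simulate_counts(
            n_genes=500, n_cells=120, n_spikes=0, libsize_cv=0.4, dispersion=0.0,
            mean_log2=6, seed=11,
        )
        factors = compute_sum_factors(exp.counts, sizes=[20, 40, 60])
        lib = np.asarray(exp.counts.sum(axis=0)).ravel()
        assert np.corrcoef(factors, lib)[0, 1] > 0.999

    def test_oversized_pools_clamped_with_warning(self, rng):
        counts, _ = no_de_counts(rng, n_cells=30)
        with pytest.warns(UserWarning, match="clamped"):
            factors = compute_sum_factors(counts, sizes=[20, 50])
        assert factors.shape == (30,)

    def test_matches_reference_deconvolution_implementation(self, tmp_path):
        """Cross-check against the Bioconductor deconvolution on a fixture."""
        exp, _ = simulate_counts(
            n_genes=120, n_cells=60, libsize_cv=0.4, dispersion=0.1,
            n_spikes=0, mean_log2=5, seed=33,
        )
        ours = compute_sum_factors(exp.counts, sizes=[10, 20, 30], min_mean=0.1)
        mat_path = tmp_path / "m.tsv"
        np.savetxt(mat_path, exp.dense_counts(), delimiter="\t", fmt="%d")
        script = (
            f'x <- as.matrix(read.table("{mat_path}"));'
            "suppressMessages(library(scran));"
            "sf <- calculateSumFactors(x, sizes=c(10,20,30), min.mean=0.1);"
            'cat(sprintf("%.12g\\n", sf))'
        )
        res = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert res.returncode == 0, res.stderr
        theirs = np.array([float(v) for v in res.stdout.split()])
        np.testing.assert_allclose(ours, theirs, atol=1e-8)

    def test_nonpositive_factor_names_cells(self):
        """Very sparse data can deconvolve to non-positive factors -> error."""
        gen = np.random.default_rng(0)
        raised = False
        for _ in range(50):
            counts = (gen.random((30, 25)) < 0.08) * gen.integers(1, 5, (30, 25))
            if (counts.sum(axis=0) == 0).any():
                continue
            try:
                compute_sum_factors(counts, sizes=[5, 10], min_mean=0)
            except ValueError as err:
                assert "cells" in str(err)
                raised = True
                break
        assert raised


class TestQuickCluster:
    def test_planted_blocks_recovered(self, rng):
        block = rng.poisson(5, size=(60, 250))
        a = np.vstack([block, np.zeros((60, 250))]) + rng.poisson(1, size=(120, 250))
        b = np.vstack([np.zeros((60, 250)), block]) + rng.poisson(1, size=(120, 250))
        counts = np.hstack([a, b])
        labels = quick_cluster(counts, min_size=200)
        assert len(np.unique(labels)) == 2
        assert len(np.unique(labels[:250])) == 1
        assert len(np.unique(labels[250:])) == 1

    def test_homogeneous_cells_one_cluster(self, rng):
        counts = rng.poisson(5, size=(50, 250))
        assert len(np.unique(quick_cluster(counts, min_size=200))) == 1

    def test_too_few_cells_rejected(self, rng):
        with pytest.raises(ValueError):
            quick_cluster(rng.poisson(5, size=(20, 150)), min_size=200)


class TestSpikeFactors:
    def _exp_with_totals(self, totals):
        counts = np.vstack([np.full(len(totals), 10), np.asarray(totals)])
        exp = build_experiment(counts, ["g1", "spike1"], None)
        exp.control_sets["S"] = np.array([False, True])
        exp.declare_spike_set("S")
        return exp

    def test_totals_divided_by_mean(self):
        exp = self._exp_with_totals([100, 200, 300])
        compute_spike_factors(exp, "S")
        np.testing.assert_allclose(exp.spike_size_factors["S"], [0.5, 1.0, 1.5])

    def test_equal_totals_give_ones(self):
        exp = self._exp_with_totals([50, 50, 50])
        compute_spike_factors(exp, "S")
        np.testing.assert_allclose(exp.spike_size_factors["S"], 1.0)

    def test_zero_totals_rejected_naming_cells(self):
        exp = self._exp_with_totals([100, 0, 300])
        with pytest.raises(ValueError, match="\\[1\\]"):
            compute_spike_factors(exp, "S")

    def test_general_use_fills_general_slot(self):
        exp = self._exp_with_totals([100, 200, 300])
        compute_spike_factors(exp, "S", general_use=True)
        np.testing.assert_allclose(exp.size_factors, [0.5, 1.0, 1.5])
        normalize_log(exp)
        # endogenous row normalized by the spike factors
        np.testing.assert_allclose(exp.log_exprs[0], np.log2(10 / np.array([0.5, 1, 1.5]) + 1))


class TestNormalizeLog:
    def _ready_exp(self):
        counts = np.array([[3, 0], [1, 8], [4, 4]])
        exp = build_experiment(counts)
        exp.size_factors = np.array([1.0, 2.0])
        return exp

    def test_hand_values(self):
        exp = normalize_log(self._ready_exp())
        assert exp.log_exprs[0, 0] == pytest.approx(2.0)  # log2(3/1 + 1)
        assert exp.log_exprs[0, 1] == 0.0  # zero count -> exactly 0
        assert exp.log_exprs[1, 1] == pytest.approx(np.log2(8 / 2 + 1))

    def test_zero_maps_to_zero_any_factor(self):
        exp = self._ready_exp()
        exp.size_factors = np.array([0.3, 17.0])
        normalize_log(exp)
        assert exp.log_exprs[0, 1] == 0.0

    def test_monotone_decreasing_in_factor(self):
        vals = [np.log2(5 / f + 1) for f in (0.5, 1, 2, 4)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_missing_general_factors_rejected(self):
        exp = build_experiment(np.ones((2, 2)))
        with pytest.raises(ValueError, match="size factors"):
            normalize_log(exp)

    def test_spike_rows_use_spike_factors(self, spiked_exp):
        spiked_exp.size_factors = np.full(30, 2.0)
        spiked_exp.spike_size_factors["ERCC"] = np.full(30, 0.5)
        normalize_log(spiked_exp)
        counts = spiked_exp.dense_counts()
        np.testing.assert_allclose(
            spiked_exp.log_exprs[20:], np.log2(counts[20:] / 0.5 + 1)
        )
        np.testing.assert_allclose(
            spiked_exp.log_exprs[:20], np.log2(counts[:20] / 2.0 + 1)
        )

    def test_missing_spike_factors_rejected(self, spiked_exp):
        spiked_exp.size_factors = np.ones(30)
        with pytest.raises(ValueError, match="spike"):
            normalize_log(spiked_exp)

    def test_output_finite_everywhere(self):
        exp, _ = simulate_counts(n_genes=50, n_cells=40, seed=7)
        deconvolve_size_factors(exp, sizes=[10, 20])
        compute_spike_factors(exp, "spike")
        normalize_log(exp)
        assert np.isfinite(exp.log_exprs).all()
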