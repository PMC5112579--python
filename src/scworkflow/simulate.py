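"""Synthetic single-cell count data with known ground truth.

Counts are negative binomial with variance mu + phi * mu^2.  Endogenous gene
means are log-normal; each cell's expected counts scale with a capture/depth
factor and, for endogenous genes only, with a cluster-specific RNA-content
factor.  Spike-in transcripts are present at constant concentration and
share the capture component but not the RNA content — the asymmetry that
makes spike-in and deconvolution size factors diverge when populations
differ in total RNA.  Cluster-specific differential expression and
phase-specific cell-cycle genes can be planted, and the full truth (factors,
labels, DE genes, dispersions) is returned alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .experiment import Experiment, build_experiment

__all__ = ["SimTruth", "simulate_counts", "simulate_cycle", "PhaseData"]


@dataclass
class SimTruth:
    """Ground truth behind a simulated experiment."""

    capture_factors: np.ndarray
    cell_factors: np.ndarray  # capture x cluster RNA content
    cluster_labels: np.ndarray
    de_genes: pd.DataFrame  # gene index, cluster, log2 fold change
    spike_concentrations: np.ndarray
    dispersion: float
    extra: Dict = field(default_factory=dict)

    def to_frames(self) -> Dict[str, pd.DataFrame]:
        cells = pd.DataFrame(
            {
                "capture_factor": self.capture_factors,
                "cell_factor": self.cell_factors,
                "cluster": self.cluster_labels,
            }
        )
        return {"cells": cells, "de_genes": self.de_genes}


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_counts(
    n_genes: int = 1000,
    n_cells: int = 200,
    n_clusters: int = 1,
    de_prob: float = 0.0,
    de_lfc: float = 2.0,
    dispersion: float = 0.1,
    libsize_cv: float = 0.3,
    n_spikes: int = 50,
    rna_content_fold: float = 1.0,
    mean_log2: float = 2.0,
    sd_log2: float = 1.5,
    hvg_extra_bio: float = 0.0,
    n_hvgs: int = 0,
    spike_fraction: float = 0.05,
    library_quantified: bool = False,
    seed: Optional[int] = None,
) -> Tuple[Experiment, SimTruth]:
    """Simulate an NB count experiment with known size factors and DE.

    Endogenous mean[g, c] = mu_g * 2^(lfc if g is DE in c's cluster)
    * capture_c * content_{cluster(c)}; spike-in mean[s, c] =
    concentration_s * capture_c, with total spike concentration scaled to
    ``spike_fraction`` of the endogenous total.  ``libsize_cv`` sets the
    coefficient of variation of the log-normal capture factors;
    ``rna_content_fold`` spreads cluster RNA content geometrically from 1 to
    the given fold.  With ``library_quantified=True`` the cDNA of every cell
    is notionally equalized before sequencing: each cell's expected total
    count is capture_c times a common baseline, and endogenous and spike-in
    molecules compete for it — so cells with more endogenous RNA get *lower*
    relative spike-in coverage, as in plate-based protocols with library
    quantification.  Optionally ``n_hvgs`` genes receive extra log-normal
    biological variability of variance ``hvg_extra_bio`` (log2 scale).
    Fully reproducible by seed.
    """
    if not 0 <= de_prob <= 1:
        raise ValueError("de_prob must lie in [0, 1]")
    if min(n_genes, n_cells, n_clusters) < 1 or n_spikes < 0:
        raise ValueError("sizes must be positive")
    rng = np.random.default_rng(seed)

    mu = 2.0 ** rng.normal(mean_log2, sd_log2, size=n_genes)
    clusters = np.repeat(np.arange(n_clusters), int(np.ceil(n_cells / n_clusters)))[:n_cells]
    if libsize_cv > 0:
        sigma = np.sqrt(np.log1p(libsize_cv**2))
        capture = rng.lognormal(-sigma**2 / 2, sigma, size=n_cells)
    else:
        capture = np.ones(n_cells)
    if n_clusters > 1 and rna_content_fold != 1.0:
        content_levels = rna_content_fold ** (np.arange(n_clusters) / (n_clusters - 1))
    else:
        content_levels = np.ones(n_clusters)
    cell_factor = capture * content_levels[clusters]

    lfc = np.zeros((n_genes, n_clusters))
    de_rows = []
    if n_clusters > 1 and de_prob > 0:
        is_de = rng.random(n_genes) < de_prob
        for g in np.flatnonzero(is_de):
            k = rng.integers(n_clusters)
            sign = rng.choice([-1.0, 1.0])
            lfc[g, k] = sign * de_lfc
            de_rows.append({"gene": g, "cluster": int(k), "lfc": sign * de_lfc})
    de_genes = pd.DataFrame(de_rows, columns=["gene", "cluster", "lfc"])

    endo_mean = mu[:, None] * 2.0 ** lfc[:, clusters] * cell_factor[None, :]
    hvg_ids = np.array([], dtype=int)
    if n_hvgs > 0 and hvg_extra_bio > 0:
        hvg_ids = rng.choice(n_genes, size=min(n_hvgs, n_genes), replace=False)
        wiggle = rng.normal(0.0, np.sqrt(hvg_extra_bio), size=(hvg_ids.size, n_cells))
        endo_mean[hvg_ids] = endo_mean[hvg_ids] * 2.0**wiggle

    spike_conc = 2.0 ** rng.normal(mean_log2, sd_log2, size=n_spikes)
    if n_spikes and spike_fraction > 0:
        spike_conc *= spike_fraction / (1 - spike_fraction) * mu.sum() / spike_conc.sum()
    spike_mean = spike_conc[:, None] * capture[None, :] if n_spikes else np.empty((0, n_cells))

    if library_quantified:
        # fixed cDNA per cell: expected total = capture * baseline, with
        # endogenous and spike-in molecules competing for the depth
        baseline = mu.sum() + spike_conc.sum()
        molecules = endo_mean.sum(axis=0) / capture + spike_conc.sum()
        depth_scale = baseline / molecules
        endo_mean = endo_mean * depth_scale
        if n_spikes:
            spike_mean = spike_mean * depth_scale
        cell_factor = cell_factor * depth_scale

    counts = _nb_draw(rng, endo_mean, dispersion)
    if n_spikes:
        counts = np.vstack([counts, _nb_draw(rng, spike_mean, dispersion)])

    feature_ids = [f"gene{i}" for i in range(n_genes)] + [f"spike{i}" for i in range(n_spikes)]
    cell_meta = pd.DataFrame(
        {"id": [f"cell{i}" for i in range(n_cells)], "cluster": clusters}
    )
    exp = build_experiment(counts, feature_ids, cell_meta)
    if n_spikes:
        spike_mask = np.zeros(n_genes + n_spikes, dtype=bool)
        spike_mask[n_genes:] = True
        exp.control_sets["spike"] = spike_mask
        exp.declare_spike_set("spike", general_use=False)

    truth = SimTruth(
        capture_factors=capture,
        cell_factors=cell_factor,
        cluster_labels=clusters,
        de_genes=de_genes,
        spike_concentrations=spike_conc,
        dispersion=dispersion,
        extra={"gene_means": mu, "hvg_genes": hvg_ids, "lfc_matrix": lfc},
    )
    return exp, truth


@dataclass
class PhaseData:
    """Expression matrix with phase labels (cell-cycle test bed)."""

    exprs: np.ndarray  # genes x cells
    genes: np.ndarray
    phases: np.ndarray


def simulate_cycle(
    n_genes: int = 200,
    cells_per_phase: int = 50,
    n_phase_genes: int = 30,
    noise_sd: float = 0.5,
    phase_effect: float = 5.0,
    seed: Optional[int] = None,
) -> Tuple[PhaseData, PhaseData, SimTruth]:
    """Simulate training and held-out test data with G1/S/G2M structure.

    For each phase, ``n_phase_genes`` genes are elevated by ``phase_effect``
    (log scale) in cells of that phase.  Baselines are strictly decreasing in
    gene order, with the unmodulated genes placed first (highest baselines)
    and the phase genes interleaved after them; with ``noise_sd=0`` this
    makes the pair-mining combinatorics exact — every phase gene paired with
    every unmodulated gene is a marker, so each phase has at least
    n_phase_genes^2 marker pairs whenever at least ``n_phase_genes``
    unmodulated genes exist (hence the 4x requirement on ``n_genes``).
    Train and test splits are disjoint draws with identical structure.
    """
    phases = ("G1", "S", "G2M")
    if n_genes < 4 * n_phase_genes:
        raise ValueError("n_genes must be at least 4 * n_phase_genes")
    rng = np.random.default_rng(seed)
    genes = np.array([f"gene{i}" for i in range(n_genes)])
    baseline = -0.01 * np.arange(n_genes)  # strictly decreasing, all distinct
    offset = n_genes - 3 * n_phase_genes
    phase_genes = {
        p: offset + i + 3 * np.arange(n_phase_genes) for i, p in enumerate(phases)
    }

    def draw() -> PhaseData:
        labels = np.repeat(phases, cells_per_phase)
        X = np.tile(baseline[:, None], (1, labels.size)).astype(float)
        for p, idx in phase_genes.items():
            X[np.ix_(idx, labels == p)] += phase_effect
        if noise_sd > 0:
            X += rng.normal(0.0, noise_sd, size=X.shape)
        return PhaseData(exprs=X, genes=genes.copy(), phases=labels)

    train, test = draw(), draw()
    truth = SimTruth(
        capture_factors=np.ones(train.phases.size),
        cell_factors=np.ones(train.phases.size),
        cluster_labels=train.phases,
        de_genes=pd.DataFrame(columns=["gene", "cluster", "lfc"]),
        spike_concentrations=np.array([]),
        dispersion=0.0,
        extra={"phase_genes": {p: v.copy() for p, v in phase_genes.items()}},
    )
    return train, test, truth
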