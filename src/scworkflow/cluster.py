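"""Cell clustering and marker-gene detection.

Cells are clustered hierarchically on Euclidean distances between their
log-expression profiles (over a chosen gene subset, typically correlated
HVGs) under Ward's criterion, and the dendrogram is cut into clusters.
Marker genes for a cluster of interest are found by testing each gene for
differential expression against every other cluster separately, then
aggregating with the min-rank ("Top") statistic: a gene's Top value is the
best rank its p-value achieves across the pairwise comparisons, so the set
of genes with Top <= t contains the t strongest candidates from every
comparison.

Two DE engines are available: a Welch t-test on log-expression, and a
negative-binomial GLM on raw counts with log size factors as offsets,
per-gene dispersion estimated by maximising the adjusted profile likelihood
on a grid, and a likelihood-ratio test for each cluster contrast.  Because
clusters are defined from the same data being tested, the p-values are
ranking scores, not calibrated significance measures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.api as sm
from scipy.cluster.hierarchy import fcluster, linkage, leaves_list
from scipy.stats import chi2, rankdata, ttest_ind

from .experiment import Experiment

__all__ = [
    "ward_tree",
    "Dendrogram",
    "cut_clusters",
    "pairwise_de",
    "rank_markers",
    "mean_centred",
]


@dataclass
class Dendrogram:
    """Ward merge history over cells plus the data it was built from."""

    linkage_matrix: np.ndarray
    data: np.ndarray  # cells x genes matrix used for clustering

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    @property
    def leaf_order(self) -> np.ndarray:
        return leaves_list(self.linkage_matrix)


def ward_tree(log_exprs, genes: Optional[Sequence[int]] = None) -> Dendrogram:
    """Agglomerative tree over cells (Ward.D2 on Euclidean distances).

    ``genes`` selects the rows (boolean mask or indices) used to describe
    each cell; merge heights are non-decreasing by the Ward property.
    """
    Y = np.asarray(log_exprs, dtype=float)
    if genes is not None:
        Y = Y[np.asarray(genes)]
    cells = Y.T
    if cells.shape[0] < 2:
        raise ValueError("need at least two cells to cluster")
    Z = linkage(cells, method="ward")
    return Dendrogram(linkage_matrix=Z, data=cells)


def cut_clusters(
    tree: Dendrogram,
    k: Optional[int] = None,
    height: Optional[float] = None,
    min_size: int = 1,
) -> np.ndarray:
    """Static cut of the dendrogram into cluster labels 1..K.

    Clusters smaller than ``min_size`` are merged into the nearest cluster
    by centroid distance; final labels are numbered by decreasing size.
    """
    if (k is None) == (height is None):
        raise ValueError("specify exactly one of k or height")
    n = tree.data.shape[0]
    if k is not None:
        if not 1 <= k <= n:
            raise ValueError(f"k must lie in [1, {n}]")
        labels = fcluster(tree.linkage_matrix, k, criterion="maxclust")
    else:
        labels = fcluster(tree.linkage_matrix, height, criterion="distance")

    labels = labels.astype(int)
    if min_size > 1:
        labels = _merge_small(labels, tree.data, min_size)
    return _relabel_by_size(labels)


def _merge_small(labels: np.ndarray, data: np.ndarray, min_size: int) -> np.ndarray:
    labels = labels.copy()
    while True:
        ids, sizes = np.unique(labels, return_counts=True)
        if len(ids) == 1 or sizes.min() >= min_size:
            break
        centroids = {i: data[labels == i].mean(axis=0) for i in ids}
        small = ids[np.argmin(sizes)]
        others = [i for i in ids if i != small]
        dists = [np.linalg.norm(centroids[small] - centroids[o]) for o in others]
        nearest = others[int(np.argmin(dists))]
        labels[labels == small] = nearest
    return labels


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    ids, sizes = np.unique(labels, return_counts=True)
    # decreasing size; ties by original id for determinism
    order = sorted(range(len(ids)), key=lambda i: (-sizes[i], ids[i]))
    mapping = {ids[i]: rank + 1 for rank, i in enumerate(order)}
    return np.array([mapping[l] for l in labels], dtype=int)


# ---------------------------------------------------------------------------
# pairwise differential expression


def _welch_comparison(Y: np.ndarray, in_target: np.ndarray, in_other: np.ndarray):
    a = Y[:, in_target]
    b = Y[:, in_other]
    with np.errstate(invalid="ignore", divide="ignore"):
        res = ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    logfc = a.mean(axis=1) - b.mean(axis=1)
    return p, logfc


_DISPERSION_GRID = np.concatenate([[1e-4], np.geomspace(0.01, 20, 18)])


def _nb_fit(y, X, offset, alpha):
    fam = sm.families.NegativeBinomial(alpha=max(alpha, 1e-8))
    model = sm.GLM(y, X, family=fam, offset=offset)
    try:
        res = model.fit(maxiter=50, tol=1e-8)
    except Exception:
        return None
    return res


def _adjusted_profile_ll(res, X) -> float:
    mu = res.fittedvalues
    alpha = res.model.family.alpha
    w = mu / (1.0 + alpha * mu)
    xtwx = X.T @ (X * w[:, None])
    sign, logdet = np.linalg.slogdet(xtwx)
    if sign <= 0:
        return -np.inf
    return res.llf - 0.5 * logdet


def _estimate_dispersion(y, X, offset, grid=_DISPERSION_GRID) -> float:
    best_alpha, best_apl = grid[0], -np.inf
    for alpha in grid:
        res = _nb_fit(y, X, offset, alpha)
        if res is None:
            continue
        apl = _adjusted_profile_ll(res, X)
        if apl > best_apl:
            best_apl, best_alpha = apl, alpha
    return float(best_alpha)


def _nb_comparison(counts, offset, labels, target, other, block_cols, dispersions):
    """Per-gene NB LRT of target vs one other cluster (cells of both only)."""
    use = (labels == target) | (labels == other)
    sub = counts[:, use]
    off = offset[use]
    is_target = (labels[use] == target).astype(float)
    ones = np.ones(use.sum())
    extra = block_cols[use] if block_cols is not None else np.empty((use.sum(), 0))
    X_full = np.column_stack([ones, is_target, extra])
    X_null = np.column_stack([ones, extra])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("confounded design: blocking factor coincides with clusters")
    ngenes = sub.shape[0]
    pvals = np.ones(ngenes)
    logfc = np.zeros(ngenes)
    for g in range(ngenes):
        y = sub[g]
        alpha = dispersions[g]
        full = _nb_fit(y, X_full, off, alpha)
        null = _nb_fit(y, X_null, off, alpha)
        if full is None or null is None:
            continue
        lr = max(0.0, 2.0 * (full.llf - null.llf))
        pvals[g] = chi2.sf(lr, 1)
        logfc[g] = full.params[1] / np.log(2)  # natural-log coefficient -> log2
    return pvals, logfc


def pairwise_de(
    exp: Experiment,
    labels,
    target_cluster,
    engine: str = "welch",
    design_extra=None,
) -> Dict[str, Dict[str, np.ndarray]]:
    """Test each gene for DE between the target cluster and every other one.

    Returns ``{"vs.<k>": {"p.value": ..., "logFC": ...}}`` with log-fold
    changes on the log2 scale, oriented target minus comparison.  The
    ``welch`` engine tests normalized log-expression; ``nb_lrt`` fits
    per-gene NB GLMs to the raw counts with log size factors as offsets and
    optional blocking columns, estimating each gene's dispersion once on the
    full dataset.
    """
    labels = np.asarray(labels)
    if labels.shape != (exp.n_cells,):
        raise ValueError("labels must have one entry per cell")
    others = [l for l in np.unique(labels) if l != target_cluster]
    if target_cluster not in labels:
        raise ValueError(f"target cluster {target_cluster!r} has no cells")
    if (labels == target_cluster).sum() < 2 or any((labels == o).sum() < 2 for o in others):
        raise ValueError("every cluster must contain at least two cells")

    results: Dict[str, Dict[str, np.ndarray]] = {}
    if engine == "welch":
        if exp.log_exprs is None:
            raise ValueError("welch engine requires log-expression; run normalize_log")
        Y = np.asarray(exp.log_exprs, dtype=float)
        for other in others:
            p, lfc = _welch_comparison(Y, labels == target_cluster, labels == other)
            results[f"vs.{other}"] = {"p.value": p, "logFC": lfc}
    elif engine == "nb_lrt":
        if exp.size_factors is None:
            raise ValueError("nb_lrt engine requires size factors")
        counts = np.asarray(exp.counts.todense(), dtype=float)
        offset = np.log(exp.size_factors)
        block_cols = None
        if design_extra is not None:
            block = np.asarray(design_extra)
            if block.dtype.kind in "OUSb":
                levels = pd.unique(block)
                block_cols = np.column_stack([(block == lev).astype(float) for lev in levels[1:]])
            else:
                block_cols = np.atleast_2d(block.astype(float))
                if block_cols.shape[0] != exp.n_cells:
                    block_cols = block_cols.T
        # one-hot cluster design (each coefficient = average log-expression of
        # its cluster) for dispersion estimation on all cells
        uniq = np.unique(labels)
        X_disp = np.column_stack(
            [(labels == u).astype(float) for u in uniq]
            + ([block_cols[:, i] for i in range(block_cols.shape[1])] if block_cols is not None else [])
        )
        dispersions = np.array(
            [_estimate_dispersion(counts[g], X_disp, offset) for g in range(exp.n_features)]
        )
        for other in others:
            p, lfc = _nb_comparison(
                counts, offset, labels, target_cluster, other, block_cols, dispersions
            )
            results[f"vs.{other}"] = {"p.value": p, "logFC": lfc}
        results["dispersions"] = dispersions  # type: ignore[assignment]
    else:
        raise ValueError(f"unknown engine {engine!r}")
    return results


def rank_markers(
    pvalues: Mapping[str, np.ndarray],
    logfcs: Mapping[str, np.ndarray],
    gene_names: Sequence[str],
    top: Optional[int] = None,
) -> pd.DataFrame:
    """Aggregate pairwise DE results into a min-rank marker table.

    Each comparison's p-values are ranked with ties broken by first
    occurrence; a gene's Top value is its minimum rank over comparisons.
    The table is sorted by Top ascending, with one ``logFC.vs.<k>`` column
    per comparison; ``top`` optionally retains only rows with Top <= top.
    """
    names = list(pvalues)
    if set(names) != set(logfcs):
        raise ValueError("p-value and logFC comparisons differ")
    genes = np.asarray([str(g) for g in gene_names])
    ranks = []
    for name in names:
        p = np.asarray(pvalues[name], dtype=float)
        if p.shape != genes.shape:
            raise ValueError("length mismatch between p-values and gene names")
        ranks.append(rankdata(p, method="ordinal"))
    min_rank = np.minimum.reduce(ranks)
    data = {"Top": min_rank.astype(int), "Gene": genes}
    for name in names:
        col = name if name.startswith("vs.") else f"vs.{name}"
        data[f"logFC.{col}"] = np.asarray(logfcs[name], dtype=float)
    table = pd.DataFrame(data).sort_values("Top", kind="stable").reset_index(drop=True)
    if top is not None:
        table = table.loc[table["Top"] <= top].reset_index(drop=True)
    return table


def mean_centred(log_exprs) -> np.ndarray:
    """Expression values mean-centred per gene (heatmap input)."""
    Y = np.asarray(log_exprs, dtype=float)
    return Y - Y.mean(axis=1, keepdims=True)
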