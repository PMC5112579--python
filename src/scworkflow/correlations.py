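"""Permutation-tested Spearman correlations and correlated-gene sets.

Pairwise Spearman correlations between (typically highly variable) genes are
tested against a permutation null: the distribution of rho between a fixed
rank vector and random permutations of it.  Because rank patterns are
exchangeable under independence, one null distribution is shared across all
pairs with the same number of cells — which is what gives every pair the
same attainable p-value floor of 2/(iterations + 1).  Significant pairs
(BH FDR) form the edges of an undirected gene graph, whose highly connected
subgraphs (edge connectivity > half the node count) are reported as
correlated gene sets.
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

__all__ = [
    "spearman_rho",
    "null_rho",
    "correlate_pairs",
    "build_gene_graph",
    "hcs_clusters",
]


def spearman_rho(x, y) -> float:
    """Spearman's rho: Pearson correlation of tie-averaged ranks.

    Returns NaN when either vector has zero rank variance (constant input).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    rx = rankdata(x)
    ry = rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def _standardize_ranks(ranks: np.ndarray) -> np.ndarray:
    """Centre and scale rank rows so pairwise dot products are correlations."""
    centred = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((centred**2).sum(axis=1))
    norms[norms == 0] = np.nan
    return centred / norms[:, None]


def null_rho(
    n_cells: int,
    iterations: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Sorted null distribution of Spearman's rho for ``n_cells`` cells.

    Draws are correlations between a fixed rank vector and independent
    uniform permutations of it; the distribution is shared across all gene
    pairs with the same number of cells.
    """
    if iterations < 1:
        raise ValueError("iterations must be at least 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    base = np.arange(n_cells, dtype=float)
    z = (base - base.mean()) / np.sqrt(((base - base.mean()) ** 2).sum())
    out = np.empty(iterations)
    chunk = max(1, min(iterations, int(4e7) // max(n_cells, 1)))
    done = 0
    while done < iterations:
        m = min(chunk, iterations - done)
        keys = rng.random((m, n_cells))
        perms = np.argsort(keys, axis=1)
        out[done : done + m] = z[perms] @ z
        done += m
    out.sort()
    return out


def _tail_count(sorted_null: np.ndarray, rho: float) -> int:
    """Null draws at least as extreme as ``rho`` in the observed direction."""
    n = sorted_null.size
    if rho >= 0:
        return n - int(np.searchsorted(sorted_null, rho, side="left"))
    return int(np.searchsorted(sorted_null, rho, side="right"))


def correlate_pairs(
    log_exprs,
    genes: Sequence[str],
    subset_genes: Optional[Sequence[str]] = None,
    design: Optional[np.ndarray] = None,
    iterations: int = 1_000_000,
    seed: Optional[int] = None,
    null: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Test all unordered gene pairs within a subset for rank correlation.

    With a ``design``, correlations are computed on the ranks of per-gene
    residuals from the design fit (an intercept-only design reproduces the
    design-free result).  The two-sided p-value is
    ``min(1, 2 (k + 1) / (N + 1))`` where ``k`` counts null draws at least
    as extreme as the observed rho in its direction, so p is floored at
    ``2 / (N + 1)``.  Rows are sorted by p, then by decreasing |rho|, and a
    BH FDR column is appended.
    """
    Y = np.asarray(log_exprs, dtype=float)
    genes = np.asarray([str(g) for g in genes])
    if Y.shape[0] != genes.size:
        raise ValueError("genes must label the rows of log_exprs")
    if subset_genes is not None:
        wanted = [str(g) for g in subset_genes]
        pos = {g: i for i, g in enumerate(genes)}
        missing = [g for g in wanted if g not in pos]
        if missing:
            raise KeyError(f"subset genes absent from the matrix: {missing[:5]}")
        idx = np.array([pos[g] for g in wanted])
        Y = Y[idx]
        genes = genes[idx]
    ngenes, ncells = Y.shape
    if ngenes < 2:
        raise ValueError("need at least two genes to correlate")

    if design is not None:
        X = np.asarray(design, dtype=float)
        Q, _ = np.linalg.qr(X)
        Y = Y - (Y @ Q) @ Q.T

    ranks = np.apply_along_axis(rankdata, 1, Y)
    Z = _standardize_ranks(ranks)
    rho_mat = Z @ Z.T

    if null is None:
        null = null_rho(ncells, iterations, seed=seed)
    else:
        null = np.sort(np.asarray(null, dtype=float))
        iterations = null.size

    i1, i2 = np.triu_indices(ngenes, k=1)
    rhos = rho_mat[i1, i2]
    pvals = np.empty(rhos.size)
    for j, r in enumerate(rhos):
        if np.isnan(r):
            pvals[j] = np.nan
            continue
        k = _tail_count(null, r)
        pvals[j] = min(1.0, 2.0 * (k + 1) / (iterations + 1))
    fdr = np.full_like(pvals, np.nan)
    ok = ~np.isnan(pvals)
    if ok.any():
        fdr[ok] = multipletests(pvals[ok], method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "gene1": genes[i1],
            "gene2": genes[i2],
            "rho": rhos,
            "p.value": pvals,
            "FDR": fdr,
        }
    )
    table["_absrho"] = -np.abs(table["rho"])
    table = table.sort_values(["p.value", "_absrho"], kind="stable").drop(columns="_absrho")
    return table.reset_index(drop=True)


def build_gene_graph(table: pd.DataFrame, fdr: float = 0.05) -> nx.Graph:
    """Undirected graph whose edges are significantly correlated gene pairs."""
    if "FDR" not in table.columns:
        raise ValueError("correlation table lacks an FDR column")
    sig = table.loc[table["FDR"] <= fdr]
    graph = nx.Graph()
    for g1, g2 in sig[["gene1", "gene2"]].itertuples(index=False):
        graph.add_edge(g1, g2)
    return graph


def _is_highly_connected(graph: nx.Graph) -> bool:
    n = graph.number_of_nodes()
    if n == 1:
        return True
    if not nx.is_connected(graph):
        return False
    if n == 2:  # a connected 2-node graph qualifies
        return True
    return nx.edge_connectivity(graph) > n / 2


def _deterministic_min_cut(graph: nx.Graph):
    """A global minimum edge cut, chosen deterministically.

    The source is the lexicographically smallest node; targets are scanned
    in sorted order and the first s-t cut achieving the global edge
    connectivity is returned, so ties between equal cuts are broken
    reproducibly.
    """
    k = nx.edge_connectivity(graph)
    nodes = sorted(graph.nodes(), key=str)
    s = nodes[0]
    for t in nodes[1:]:
        cut = nx.minimum_edge_cut(graph, s, t)
        if len(cut) == k:
            return cut
    raise AssertionError("global min cut not found")  # pragma: no cover


def hcs_clusters(graph: nx.Graph) -> List[List[str]]:
    """Highly-connected-subgraph decomposition into gene sets.

    A connected subgraph with n nodes is highly connected when its edge
    connectivity exceeds n/2 (a connected 2-node graph qualifies); other
    subgraphs are split along a global minimum edge cut and both sides
    processed recursively.  Singletons are discarded and clusters returned
    largest first.
    """
    clusters: List[List[str]] = []

    def process(sub: nx.Graph):
        if sub.number_of_nodes() == 1:
            return
        for comp in [sub.subgraph(c).copy() for c in nx.connected_components(sub)]:
            if comp.number_of_nodes() == 1:
                continue
            if _is_highly_connected(comp):
                clusters.append(sorted(comp.nodes(), key=str))
                continue
            cut = _deterministic_min_cut(comp)
            comp.remove_edges_from(cut)
            process(comp)

    if graph.number_of_nodes():
        process(graph.copy())
    clusters.sort(key=lambda c: (-len(c), c))
    return clusters
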