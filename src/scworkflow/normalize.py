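"""Size-factor estimation and log-normalization.

Counts are subject to cell-specific capture and sequencing-depth biases.
Assuming most genes are not differentially expressed, per-cell size factors
are estimated and counts divided by them before log-transformation.

Two estimators are provided:

* **Deconvolution** — counts are pooled across rings of cells to overcome the
  dominance of zeros; robust (median-based) pool-level factors are then
  deconvolved back into per-cell factors by solving a sparse linear system.
  For heterogeneous populations, cells are pre-clustered and normalized
  within clusters, with clusters rescaled to a common reference afterwards.
* **Spike-in factors** — proportional to each cell's total count over a
  spike-in set.  Because the same quantity of spike-in RNA is added to every
  cell, these capture technical bias only and, unlike deconvolution factors,
  preserve differences in total RNA content between cells.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .experiment import Experiment

__all__ = [
    "quick_cluster",
    "compute_sum_factors",
    "deconvolve_size_factors",
    "compute_spike_factors",
    "normalize_log",
]

# Relative weight of the per-cell library-size equations that complete the
# rank of the pool system; any positive value is exact on no-DE data.
_LOW_WEIGHT = 1e-6


def quick_cluster(counts, min_size: int = 200) -> np.ndarray:
    """Crude pre-clustering of cells for within-cluster normalization.

    Distances between cells are sqrt((1 - rho)/2) with rho the Spearman
    correlation of their expression profiles, which is robust to both noise
    and normalization errors.  An average-linkage tree is cut at the lowest
    level at which every cluster still has at least ``min_size`` cells.
    Returns integer labels starting at 0, deterministic given the input.
    """
    counts = counts.counts if isinstance(counts, Experiment) else counts
    dense = np.asarray(counts.todense()) if sp.issparse(counts) else np.asarray(counts, float)
    n = dense.shape[1]
    if n < min_size:
        raise ValueError(f"need at least min_size={min_size} cells, got {n}")
    ranks = np.apply_along_axis(rankdata, 0, dense)
    ranks = ranks - ranks.mean(axis=0)
    norms = np.sqrt((ranks**2).sum(axis=0))
    norms[norms == 0] = 1.0
    rho = np.clip((ranks / norms).T @ (ranks / norms), -1.0, 1.0)
    dist = np.sqrt(np.maximum(0.0, (1.0 - rho) / 2.0))
    np.fill_diagonal(dist, 0.0)
    tree = linkage(squareform(dist, checks=False), method="average")
    for k in range(n // min_size, 0, -1):
        labels = fcluster(tree, k, criterion="maxclust")
        sizes = np.bincount(labels)[1:]
        if (sizes >= min_size).all() and len(sizes) == k:
            break
    # relabel in order of first appearance for determinism
    _, first_seen = np.unique(labels, return_index=True)
    order = {labels[i]: rank for rank, i in enumerate(sorted(first_seen))}
    return np.array([order[l] for l in labels], dtype=int)


def _generate_ring(lib_sizes: np.ndarray) -> np.ndarray:
    """Arrange cells on a ring ordered by library size.

    Cells are sorted by library size and interleaved (odd positions ascending,
    even positions descending) so that each pool window mixes small and large
    libraries; the ring is doubled so windows can wrap around.
    """
    o = np.argsort(lib_sizes, kind="stable")
    out = np.concatenate([o[0::2], o[1::2][::-1]])
    return np.concatenate([out, out])


def _cluster_sum_factors(counts, sizes: Sequence[int], min_mean: float):
    """Deconvolution factors for one cluster.

    Returns (size factors, full-gene average profile) where the profile is
    the per-gene average of library-size-scaled cells times the mean library
    size (a pseudo-cell used for cross-cluster rescaling).
    """
    dense = np.asarray(counts.todense(), dtype=float) if sp.issparse(counts) else np.asarray(counts, dtype=float)
    ngenes, ncells = dense.shape
    lib = dense.sum(axis=0)
    if np.any(lib <= 0):
        bad = np.flatnonzero(lib <= 0)
        raise ValueError(f"cells with zero library size: {bad.tolist()}")
    scaled = dense / lib  # each column sums to 1
    profile = scaled.mean(axis=1) * lib.mean()

    keep = profile >= max(min_mean, np.finfo(float).tiny)
    if not keep.any():
        raise ValueError("no genes pass min_mean within a cluster")
    E = scaled[keep]
    ave = profile[keep]

    use_sizes = sorted({min(int(s), ncells) for s in sizes if s >= 1})
    if any(s > ncells for s in sizes):
        warnings.warn(f"pool sizes clamped to the {ncells} available cells")
    if not use_sizes:
        raise ValueError("no valid pool sizes")

    ring = _generate_ring(lib)
    ordered = E[:, ring]  # genes x 2*ncells
    csum = np.concatenate([np.zeros((E.shape[0], 1)), np.cumsum(ordered, axis=1)], axis=1)

    rows, cols, vals, rhs = [], [], [], []
    eq = 0
    for s in use_sizes:
        for start in range(ncells):
            pooled = csum[:, start + s] - csum[:, start]
            theta = np.median(pooled / ave)
            members = ring[start : start + s]
            rows.extend([eq] * s)
            cols.extend(members.tolist())
            vals.extend([1.0] * s)
            rhs.append(theta)
            eq += 1
    # low-weight per-cell equations for full rank: nf_c ~ 1/sum(ave)
    w = np.sqrt(_LOW_WEIGHT)
    target = w / ave.sum()
    for c in range(ncells):
        rows.append(eq)
        cols.append(c)
        vals.append(w)
        rhs.append(target)
        eq += 1

    A = sp.csr_matrix((vals, (rows, cols)), shape=(eq, ncells))
    b = np.asarray(rhs)
    if ncells <= 1200:
        nf, *_ = np.linalg.lstsq(A.toarray(), b, rcond=None)
    else:
        nf = sp.linalg.lsqr(A, b, atol=1e-12, btol=1e-12, iter_lim=8 * ncells)[0]
    factors = nf * lib
    if np.any(factors <= 0):
        bad = np.flatnonzero(factors <= 0)
        raise ValueError(
            f"non-positive size factors for cells {bad.tolist()}; "
            "consider more aggressive gene filtering or larger pools"
        )
    return factors, profile


def _rescale_clusters(profiles, ref: int, min_mean: float) -> np.ndarray:
    """Median-ratio rescaling factors putting clusters on a common scale."""
    out = np.empty(len(profiles))
    ref_prof = profiles[ref]
    ref_lib = ref_prof.sum()
    for i, cur in enumerate(profiles):
        cur_lib = cur.sum()
        grand = (cur / cur_lib + ref_prof / ref_lib) / 2 * (cur_lib + ref_lib) / 2
        use = grand >= min_mean
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = cur[use] / ref_prof[use]
        ratios = ratios[np.isfinite(ratios)]
        rescale = np.median(ratios) if ratios.size else np.nan
        if not np.isfinite(rescale) or rescale <= 0:
            warnings.warn(
                f"rescaling factor for cluster {i} not strictly positive; "
                "falling back to the ratio of average library sizes"
            )
            rescale = cur_lib / ref_lib
        out[i] = rescale
    return out


def compute_sum_factors(
    counts,
    sizes: Sequence[int] = (20, 40, 60, 80),
    clusters: Optional[np.ndarray] = None,
    min_mean: float = 0.1,
) -> np.ndarray:
    """Per-cell size factors by pooling and deconvolution.

    Counts from rings of cells are pooled to obtain stable, median-based
    pool factors, which are deconvolved into per-cell factors by least
    squares.  With ``clusters`` given, cells are normalized within each
    cluster and clusters rescaled by the median ratio of their pseudo-cells,
    so factors are comparable across clusters.  The result is centred to
    mean 1.
    """
    counts = counts.counts if isinstance(counts, Experiment) else counts
    mat = counts.tocsc() if sp.issparse(counts) else sp.csc_matrix(np.asarray(counts, dtype=float))
    ncells = mat.shape[1]
    if clusters is None:
        clusters = np.zeros(ncells, dtype=int)
    clusters = np.asarray(clusters)
    if clusters.shape != (ncells,):
        raise ValueError("cluster labels must have one entry per cell")

    labels = np.unique(clusters)
    factors = np.empty(ncells)
    profiles = []
    index_sets = []
    for lab in labels:
        idx = np.flatnonzero(clusters == lab)
        f, profile = _cluster_sum_factors(mat[:, idx], sizes, min_mean)
        factors[idx] = f
        profiles.append(profile)
        index_sets.append(idx)

    if len(labels) > 1:
        ref = int(np.argmax([np.count_nonzero(p) for p in profiles]))
        rescaling = _rescale_clusters(profiles, ref, min_mean)
        for idx, r in zip(index_sets, rescaling):
            factors[idx] *= r
    return factors / factors.mean()


def deconvolve_size_factors(exp: Experiment, sizes: Sequence[int] = (20, 40, 60, 80), clusters=None, min_mean: float = 0.1) -> Experiment:
    """Store deconvolution size factors (endogenous genes only) on ``exp``."""
    endo = exp.endogenous_mask
    exp.size_factors = compute_sum_factors(exp.counts[endo], sizes=sizes, clusters=clusters, min_mean=min_mean)
    return exp


def compute_spike_factors(exp: Experiment, set_name: str, general_use: Optional[bool] = None) -> Experiment:
    """Size factors proportional to each cell's total spike-in count.

    Every cell must have at least one spike count.  Factors are centred to
    mean 1 and stored in the spike slot; with ``general_use`` they are also
    copied to the general slot and applied to all features downstream.
    """
    if set_name not in exp.spike_sets:
        raise KeyError(f"{set_name!r} is not a declared spike set")
    if general_use is None:
        general_use = exp.spike_sets[set_name]
    else:
        exp.spike_sets[set_name] = bool(general_use)
    mask = exp.control_sets[set_name]
    totals = np.asarray(exp.counts[mask].sum(axis=0)).ravel().astype(float)
    if np.any(totals <= 0):
        bad = np.flatnonzero(totals <= 0)
        raise ValueError(f"cells with zero spike-in counts for {set_name!r}: {bad.tolist()}")
    factors = totals / totals.mean()
    exp.spike_size_factors[set_name] = factors
    if general_use:
        exp.size_factors = factors.copy()
    return exp


def normalize_log(exp: Experiment, pseudocount: float = 1.0, base: float = 2.0) -> Experiment:
    """Compute normalized log-expression values.

    Each value is ``log_base(count / size_factor + pseudocount)``.  Spike-in
    rows are normalized by their own spike-set factors unless the set was
    declared ``general_use``; endogenous rows always use the general slot.
    With the default pseudocount of 1, zero counts map to exactly 0.
    """
    if exp.size_factors is None:
        raise ValueError("general size factors are required; compute them first")
    row_factors = {}
    for name, general in exp.spike_sets.items():
        if general:
            continue
        if name not in exp.spike_size_factors:
            raise ValueError(f"spike set {name!r} lacks size factors; run compute_spike_factors")
        row_factors[name] = exp.spike_size_factors[name]

    log_base = np.log(base)
    dense = np.asarray(exp.counts.todense(), dtype=float)
    out = np.log(dense / exp.size_factors + pseudocount) / log_base
    for name, factors in row_factors.items():
        mask = exp.control_sets[name]
        out[mask] = np.log(dense[mask] / factors + pseudocount) / log_base
    exp.log_exprs = out
    return exp
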