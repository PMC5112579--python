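"""Abundance-based feature filtering.

Low-abundance genes are dominated by drop-out events and their near-zero
counts carry little information, so they are removed before normalization
and variance modelling.  Two rules are provided: keep genes whose mean raw
count reaches a threshold (1 for read counts, lower for UMI data), or keep
genes expressed in at least ``n`` cells.  The mean-based rule is usually
preferred: it retains genes with sufficient expression in any subset of
cells rather than imposing a hard cell-count floor that can hide rare
subpopulations.
"""

from __future__ import annotations

import numpy as np

from .experiment import Experiment

__all__ = ["mean_filter", "ncells_filter", "drop_feature_set"]


def mean_filter(exp: Experiment, threshold: float = 1.0) -> np.ndarray:
    """Keep features whose mean raw count across cells is >= ``threshold``."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    means = np.asarray(exp.counts.mean(axis=1)).ravel()
    return means >= threshold


def ncells_filter(exp: Experiment, n: int) -> np.ndarray:
    """Keep features with non-zero counts in at least ``n`` cells."""
    if not 1 <= n <= exp.n_cells:
        raise ValueError(f"n must lie in [1, {exp.n_cells}]")
    ncells = exp.counts.getnnz(axis=1)
    return ncells >= n


def drop_feature_set(exp: Experiment, set_name: str) -> Experiment:
    """Remove every feature in a named control set (e.g. mitochondrial genes).

    If the set was declared as a spike-in set, its registration and any
    stored spike size factors are removed with it.
    """
    if set_name not in exp.control_sets:
        raise KeyError(f"unknown feature set {set_name!r}")
    mask = exp.control_sets[set_name]
    if not mask.any():
        return exp
    out = exp.subset(feature_mask=~mask)
    out.control_sets.pop(set_name, None)
    out.spike_sets.pop(set_name, None)
    out.spike_size_factors.pop(set_name, None)
    return out
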