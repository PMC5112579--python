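"""Per-cell quality control.

Library size (total counts over all features), the number of expressed
features, and the percentage of counts assigned to each control set (e.g.
mitochondrial genes or spike-in transcripts) are the core metrics.  Cells are
flagged as low quality when a metric lies more than ``nmads`` median absolute
deviations from the median in the suspect direction — an adaptive threshold
that assumes most of the dataset consists of high-quality cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .experiment import Experiment

__all__ = [
    "compute_qc_metrics",
    "is_outlier",
    "apply_cell_filters",
    "qc_metric_pca",
    "FilterSummary",
]

# Consistency constant making the MAD an unbiased estimate of the standard
# deviation under normality; matches the convention of R's mad().
MAD_SCALE = 1.4826


def compute_qc_metrics(exp: Experiment, control_sets: Optional[Sequence[str]] = None) -> Experiment:
    """Append QC metric columns to the cell table (idempotent).

    Adds ``total_counts``, ``total_features`` and one ``pct_counts_<set>``
    column per control set, the percentage (0-100) of each cell's total
    counts assigned to that set.  All-zero cells get percentage 0.
    """
    if control_sets is None:
        control_sets = list(exp.control_sets)
    masks = {}
    for name in control_sets:
        if name not in exp.control_sets:
            raise KeyError(f"unknown control set {name!r}")
        masks[name] = exp.control_sets[name]
    taken = np.zeros(exp.n_features, dtype=bool)
    for name, mask in masks.items():
        if (taken & mask).any():
            warnings.warn("control sets overlap; percentages may double-count")
        taken |= mask

    counts = exp.counts.tocsc()
    total = np.asarray(counts.sum(axis=0)).ravel()
    nfeat = counts.getnnz(axis=0)
    exp.cell_table["total_counts"] = total
    exp.cell_table["total_features"] = nfeat
    safe_total = np.where(total > 0, total, 1.0)
    for name, mask in masks.items():
        in_set = np.asarray(counts[mask].sum(axis=0)).ravel()
        pct = 100.0 * in_set / safe_total
        pct[total == 0] = 0.0
        exp.cell_table[f"pct_counts_{name}"] = pct
        exp.cell_table[f"counts_{name}"] = in_set
    return exp


def is_outlier(
    values,
    nmads: float = 3.0,
    side: str = "both",
    log: bool = False,
) -> np.ndarray:
    """Flag values more than ``nmads`` MADs from the median.

    ``side`` selects the suspect direction (``lower``, ``higher`` or
    ``both``).  With ``log=True`` the test operates on natural-log values
    (zero maps to -inf and is always caught by lower-side tests); the flagged
    set does not depend on the log base.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot call outliers on an empty vector")
    if side not in ("lower", "higher", "both"):
        raise ValueError(f"unknown side {side!r}")
    if log:
        if np.any(values < 0):
            raise ValueError("log transform requires non-negative values")
        with np.errstate(divide="ignore"):
            values = np.log(values)
    med = np.median(values)
    mad = MAD_SCALE * np.median(np.abs(values - med))
    flags = np.zeros(values.shape, dtype=bool)
    if side in ("lower", "both"):
        flags |= values < med - nmads * mad
    if side in ("higher", "both"):
        flags |= values > med + nmads * mad
    return flags


@dataclass
class FilterSummary:
    """Number of cells flagged by each filter and the surviving count."""

    counts: Dict[str, int]
    remaining: int

    def to_frame(self) -> pd.DataFrame:
        data = {name: [n] for name, n in self.counts.items()}
        data["Remaining"] = [self.remaining]
        return pd.DataFrame(data, index=["Samples"])


def apply_cell_filters(
    exp: Experiment, masks: Mapping[str, np.ndarray]
) -> Tuple[Experiment, FilterSummary]:
    """Drop cells flagged by any filter mask; report per-filter counts.

    Removal of a substantial proportion of cells (> 10%) triggers a warning,
    as it may indicate an overall data-quality problem.
    """
    drop = np.zeros(exp.n_cells, dtype=bool)
    counts = {}
    for name, mask in masks.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (exp.n_cells,):
            raise ValueError(f"filter {name!r} not aligned to cells")
        counts[name] = int(mask.sum())
        drop |= mask
    summary = FilterSummary(counts=counts, remaining=int((~drop).sum()))
    if drop.sum() > 0.1 * exp.n_cells:
        warnings.warn(
            f"removal of a substantial proportion of cells "
            f"({drop.sum()}/{exp.n_cells} > 10%) — check data quality"
        )
    filtered = exp.subset(cell_mask=~drop) if drop.any() else exp
    return filtered, summary


def qc_metric_pca(exp: Experiment, metrics: Optional[Sequence[str]] = None) -> np.ndarray:
    """Coordinates of cells on the first two PCs of the standardized QC metrics.

    Deterministic up to sign; the sign is fixed so that each component's
    largest-magnitude loading is positive.  Constant metrics are ignored.
    """
    if metrics is None:
        metrics = [
            c
            for c in exp.cell_table.columns
            if c in ("total_counts", "total_features") or c.startswith("pct_counts_")
        ]
    if not metrics:
        raise ValueError("no QC metrics present; run compute_qc_metrics first")
    if exp.n_cells < 3:
        raise ValueError("QC PCA requires at least 3 cells")
    X = exp.cell_table[list(metrics)].to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    X = X[:, keep] / sd[keep]
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    coords = u[:, :2] * s[:2]
    if coords.shape[1] < 2:  # fewer than two informative metrics
        coords = np.column_stack([coords, np.zeros(len(coords))])[:, :2]
    for j in range(coords.shape[1]):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            coords[:, j] = -coords[:, j]
    return coords
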