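"""Count-experiment container for single-cell RNA-seq pipelines.

An :class:`Experiment` holds a feature-by-cell count matrix together with
per-feature and per-cell annotation tables, named control sets (e.g. ERCC
spike-ins or mitochondrial genes), per-cell size factors, and an optional
matrix of normalized log-expression values.  All slots share the feature and
cell dimensions; subsetting by either dimension keeps every slot aligned.

Counts are stored sparsely (CSR); dense inputs are accepted and converted.
Feature identity is positional — row order is authoritative and feature names
may repeat (a warning is emitted), as is common for symbol-keyed public data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["Experiment", "IdMapping", "build_experiment", "map_ids"]


def _as_sparse(matrix) -> sp.csr_matrix:
    if sp.issparse(matrix):
        return matrix.tocsr()
    arr = np.asarray(matrix)
    if arr.ndim != 2:
        raise ValueError("count matrix must be two-dimensional")
    return sp.csr_matrix(arr)


def _as_mask(values, length: int, what: str) -> np.ndarray:
    mask = np.asarray(values)
    if mask.dtype == bool:
        if mask.shape != (length,):
            raise ValueError(f"{what} mask has length {mask.shape}, expected {length}")
        return mask
    # integer indices
    out = np.zeros(length, dtype=bool)
    out[mask] = True
    return out


@dataclass
class Experiment:
    """Feature x cell count experiment with aligned annotation slots.

    Attributes
    ----------
    counts
        Non-negative feature-by-cell matrix (CSR sparse).
    feature_table
        One row per feature; must contain an ``id`` column.
    cell_table
        One row per cell; QC metrics are appended here once computed.
    control_sets
        Named boolean feature masks (e.g. ``"ERCC"``, ``"Mt"``).
    spike_sets
        Subset of control-set names declared as spike-ins, mapped to their
        ``general_use`` flag (whether their size factors apply to all genes).
    size_factors
        Per-cell positive scaling factors (general slot), mean 1 when set.
    spike_size_factors
        Per spike-set per-cell factors, mean 1 when set.
    log_exprs
        Optional feature-by-cell matrix of normalized log-expression.
    """

    counts: sp.csr_matrix
    feature_table: pd.DataFrame
    cell_table: pd.DataFrame
    control_sets: Dict[str, np.ndarray] = field(default_factory=dict)
    spike_sets: Dict[str, bool] = field(default_factory=dict)
    size_factors: Optional[np.ndarray] = None
    spike_size_factors: Dict[str, np.ndarray] = field(default_factory=dict)
    log_exprs: Optional[np.ndarray] = None

    def __post_init__(self):
        self.counts = _as_sparse(self.counts)
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("count matrix contains negative entries")
        nf, nc = self.counts.shape
        if len(self.feature_table) != nf:
            raise ValueError(
                f"feature table has {len(self.feature_table)} rows for {nf} features"
            )
        if len(self.cell_table) != nc:
            raise ValueError(
                f"cell table has {len(self.cell_table)} rows for {nc} cells"
            )
        if nc == 0:
            raise ValueError("experiment must contain at least one cell")
        if "id" not in self.feature_table.columns:
            raise ValueError("feature table must contain an 'id' column")
        self.feature_table = self.feature_table.reset_index(drop=True)
        self.cell_table = self.cell_table.reset_index(drop=True)
        if self.feature_table["id"].duplicated().any():
            warnings.warn("duplicate feature ids present; row order is authoritative")
        for name, mask in list(self.control_sets.items()):
            self.control_sets[name] = _as_mask(mask, nf, f"control set {name!r}")
        self._check_spike_sets()
        if self.size_factors is not None:
            self.size_factors = self._check_factors(self.size_factors, "size_factors")
        for name, f in list(self.spike_size_factors.items()):
            self.spike_size_factors[name] = self._check_factors(
                f, f"spike_size_factors[{name!r}]"
            )
        if self.log_exprs is not None and self.log_exprs.shape != (nf, nc):
            raise ValueError("log_exprs shape does not match counts")

    def _check_spike_sets(self):
        taken = np.zeros(self.n_features, dtype=bool)
        for name in self.spike_sets:
            if name not in self.control_sets:
                raise KeyError(f"spike set {name!r} is not a declared control set")
            mask = self.control_sets[name]
            if (taken & mask).any():
                raise ValueError("spike sets overlap: each feature may belong to at most one")
            taken |= mask

    def _check_factors(self, values, what: str) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_cells,):
            raise ValueError(f"{what} must have one value per cell")
        if not np.all(values > 0):
            raise ValueError(f"{what} must be strictly positive")
        return values

    # -- basic geometry -------------------------------------------------
    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def dims(self) -> Tuple[int, int]:
        """Dimension report: (features, cells)."""
        return self.counts.shape

    @property
    def feature_ids(self) -> np.ndarray:
        return self.feature_table["id"].to_numpy()

    # -- spike handling -------------------------------------------------
    def declare_spike_set(self, set_name: str, general_use: bool = False) -> "Experiment":
        """Register a control set as a spike-in set.

        Spike-in transcripts are added in constant quantity per cell, so
        their counts reflect technical bias only and require separate
        treatment during normalization.  With ``general_use=True`` the
        spike-derived size factors are applied to all features; otherwise
        they are used for the spike-in rows only.
        """
        if set_name not in self.control_sets:
            raise KeyError(f"unknown control set {set_name!r}")
        self.spike_sets[set_name] = bool(general_use)
        self._check_spike_sets()
        return self

    def spike_mask(self, set_name: Optional[str] = None) -> np.ndarray:
        """Boolean mask of spike-in features (one set, or the union)."""
        if set_name is not None:
            if set_name not in self.spike_sets:
                raise KeyError(f"{set_name!r} is not a declared spike set")
            return self.control_sets[set_name].copy()
        mask = np.zeros(self.n_features, dtype=bool)
        for name in self.spike_sets:
            mask |= self.control_sets[name]
        return mask

    @property
    def endogenous_mask(self) -> np.ndarray:
        """Features that are not part of any declared spike set."""
        return ~self.spike_mask()

    # -- subsetting -----------------------------------------------------
    def subset(self, feature_mask=None, cell_mask=None) -> "Experiment":
        """Subset features and/or cells, keeping every slot aligned.

        Size factors are carried over as-is (no re-centring); centring to
        mean 1 happens only when factors are (re)computed.
        """
        exp = self
        if feature_mask is not None:
            exp = exp._subset_features(_as_mask(feature_mask, exp.n_features, "feature"))
        if cell_mask is not None:
            exp = exp._subset_cells(_as_mask(cell_mask, exp.n_cells, "cell"))
        return exp

    def _subset_features(self, mask: np.ndarray) -> "Experiment":
        if not mask.any():
            raise ValueError("feature mask removes every feature")
        return Experiment(
            counts=self.counts[mask],
            feature_table=self.feature_table.loc[mask].reset_index(drop=True),
            cell_table=self.cell_table.copy(),
            control_sets={k: v[mask] for k, v in self.control_sets.items()},
            spike_sets=dict(self.spike_sets),
            size_factors=None if self.size_factors is None else self.size_factors.copy(),
            spike_size_factors={k: v.copy() for k, v in self.spike_size_factors.items()},
            log_exprs=None if self.log_exprs is None else self.log_exprs[mask],
        )

    def _subset_cells(self, mask: np.ndarray) -> "Experiment":
        if not mask.any():
            raise ValueError("cell mask removes every cell")
        return Experiment(
            counts=self.counts[:, mask],
            feature_table=self.feature_table.copy(),
            cell_table=self.cell_table.loc[mask].reset_index(drop=True),
            control_sets={k: v.copy() for k, v in self.control_sets.items()},
            spike_sets=dict(self.spike_sets),
            size_factors=None if self.size_factors is None else self.size_factors[mask],
            spike_size_factors={k: v[mask] for k, v in self.spike_size_factors.items()},
            log_exprs=None if self.log_exprs is None else self.log_exprs[:, mask],
        )

    def copy(self) -> "Experiment":
        return Experiment(
            counts=self.counts.copy(),
            feature_table=self.feature_table.copy(),
            cell_table=self.cell_table.copy(),
            control_sets={k: v.copy() for k, v in self.control_sets.items()},
            spike_sets=dict(self.spike_sets),
            size_factors=None if self.size_factors is None else self.size_factors.copy(),
            spike_size_factors={k: v.copy() for k, v in self.spike_size_factors.items()},
            log_exprs=None if self.log_exprs is None else self.log_exprs.copy(),
        )

    # -- metadata access ------------------------------------------------
    def cell_column(self, name: str) -> np.ndarray:
        """Fetch a cell-metadata column; missing columns raise immediately."""
        if name not in self.cell_table.columns:
            raise KeyError(f"cell metadata column {name!r} is not present")
        return self.cell_table[name].to_numpy()

    def dense_counts(self) -> np.ndarray:
        return np.asarray(self.counts.todense())


def build_experiment(counts, feature_meta=None, cell_meta=None) -> Experiment:
    """Assemble an :class:`Experiment` from a count matrix and metadata.

    ``feature_meta`` / ``cell_meta`` may be data frames, sequences of ids, or
    ``None`` (ids are generated).  Dimensions must agree with the matrix.
    """
    counts = _as_sparse(counts)
    nf, nc = counts.shape

    def _table(meta, n, prefix, axis):
        if meta is None:
            return pd.DataFrame({"id": [f"{prefix}{i}" for i in range(n)]})
        if isinstance(meta, pd.DataFrame):
            t = meta.reset_index(drop=True).copy()
            if "id" not in t.columns:
                t.insert(0, "id", [f"{prefix}{i}" for i in range(len(t))])
        else:
            t = pd.DataFrame({"id": list(meta)})
        if len(t) != n:
            raise ValueError(f"{axis} metadata has {len(t)} rows for {n} {axis}s")
        return t

    return Experiment(
        counts=counts,
        feature_table=_table(feature_meta, nf, "gene", "feature"),
        cell_table=_table(cell_meta, nc, "cell", "cell"),
    )


class IdMapping:
    """Ordered (source id -> symbol) mapping with a first-match rule.

    Public annotation tables are often many-to-many; when several symbols
    correspond to one id, the first in mapping order wins, so lookup is
    deterministic.
    """

    def __init__(self, pairs: Iterable[Tuple[str, str]]):
        self._first: Dict[str, str] = {}
        self.pairs: List[Tuple[str, str]] = []
        for src, tgt in pairs:
            self.pairs.append((src, tgt))
            if src not in self._first and tgt is not None and not (
                isinstance(tgt, float) and np.isnan(tgt)
            ):
                self._first[src] = tgt

    def lookup(self, source_id: str) -> Optional[str]:
        return self._first.get(source_id)


def map_ids(ids: Sequence[str], mapping: IdMapping) -> List[Optional[str]]:
    """Map each id to its first matching symbol; unmapped ids yield ``None``."""
    return [mapping.lookup(i) for i in ids]
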