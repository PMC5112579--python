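"""Readers and writers for the on-disk formats the pipeline touches.

Count matrices are exchanged as MatrixMarket coordinate files with sidecar
feature/cell id text files, or as delimited tables (TSV/CSV, optionally
gzipped) with a header row and the feature id in the first column.  An
:class:`~scworkflow.experiment.Experiment` persists as a directory bundle so
pipeline stages can resume from disk.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .experiment import Experiment

__all__ = [
    "read_counts",
    "write_counts",
    "write_table",
    "save_bundle",
    "load_bundle",
]


def _infer_format(path: Path) -> str:
    suffixes = [s.lower() for s in path.suffixes]
    if ".mtx" in suffixes:
        return "matrixmarket"
    return "delimited"


def _delim_for(path: Path) -> str:
    name = path.name.lower()
    return "," if name.endswith(".csv") or name.endswith(".csv.gz") else "\t"


def read_counts(path, format: Optional[str] = None, delimiter: Optional[str] = None):
    """Read a feature x cell count matrix.

    Returns ``(matrix, feature_ids, cell_ids)``; the matrix is CSR sparse.
    MatrixMarket files keep explicit zeros as structural entries and expect
    sidecar ``<stem>.features.txt`` / ``<stem>.cells.txt`` id files (ids are
    generated when the sidecars are absent).  Delimited files must carry a
    header row of cell ids and feature ids in the first column.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "matrixmarket":
        mat = scipy.io.mmread(str(path))
        mat = sp.csr_matrix(mat)
        stem = path.name
        for suff in (".gz", ".mtx"):
            if stem.endswith(suff):
                stem = stem[: -len(suff)]
        fpath = path.with_name(stem + ".features.txt")
        cpath = path.with_name(stem + ".cells.txt")
        feature_ids = (
            fpath.read_text().split() if fpath.exists() else [f"gene{i}" for i in range(mat.shape[0])]
        )
        cell_ids = (
            cpath.read_text().split() if cpath.exists() else [f"cell{i}" for i in range(mat.shape[1])]
        )
    elif fmt == "delimited":
        delim = delimiter or _delim_for(path)
        table = pd.read_csv(path, sep=delim, header=0, index_col=0)
        values = table.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError(f"non-numeric entries in count table {path}")
        mat = sp.csr_matrix(values)
        feature_ids = [str(x) for x in table.index]
        cell_ids = [str(x) for x in table.columns]
    else:
        raise ValueError(f"unknown count format {fmt!r}")
    if len(feature_ids) != mat.shape[0] or len(cell_ids) != mat.shape[1]:
        raise ValueError("id sidecars do not match matrix dimensions")
    if len(set(feature_ids)) != len(feature_ids):
        import warnings

        warnings.warn("duplicate feature ids in count file; keeping all rows")
    return mat, feature_ids, cell_ids


def write_counts(matrix, feature_ids: Sequence[str], cell_ids: Sequence[str], path, format: Optional[str] = None):
    """Write a count matrix; exact integer round trip with :func:`read_counts`."""
    path = Path(path)
    fmt = format or _infer_format(path)
    matrix = matrix if sp.issparse(matrix) else sp.csr_matrix(np.asarray(matrix))
    if fmt == "matrixmarket":
        scipy.io.mmwrite(str(path), matrix.tocoo())
        stem = path.name
        for suff in (".gz", ".mtx"):
            if stem.endswith(suff):
                stem = stem[: -len(suff)]
        path.with_name(stem + ".features.txt").write_text("\n".join(map(str, feature_ids)) + "\n")
        path.with_name(stem + ".cells.txt").write_text("\n".join(map(str, cell_ids)) + "\n")
    elif fmt == "delimited":
        dense = np.asarray(matrix.todense())
        table = pd.DataFrame(dense, index=list(feature_ids), columns=list(cell_ids))
        table.to_csv(path, sep=_delim_for(path))
    else:
        raise ValueError(f"unknown count format {fmt!r}")


def write_table(table: pd.DataFrame, path, index: bool = False):
    """Write a result table as tab-separated text.

    Used for HVG tables (name, mean, total, bio, tech, p.value, FDR),
    correlation tables (gene1, gene2, rho, p.value, FDR) and marker tables
    (Top, Gene, logFC.vs.<k>...).
    """
    table.to_csv(path, sep="\t", index=index)


# -- Experiment directory bundles ---------------------------------------

def save_bundle(exp: Experiment, directory):
    """Persist an Experiment as a directory of plain-text files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_counts(
        exp.counts,
        exp.feature_ids,
        exp.cell_table["id"].tolist(),
        directory / "counts.mtx",
    )
    ftab = exp.feature_table.copy()
    for name, mask in exp.control_sets.items():
        ftab[f"set:{name}"] = mask
    ftab.to_csv(directory / "features.tsv", sep="\t", index=False)
    exp.cell_table.to_csv(directory / "cells.tsv", sep="\t", index=False)
    meta = {"spike_sets": exp.spike_sets}
    (directory / "meta.json").write_text(json.dumps(meta, indent=1))
    sf = pd.DataFrame({"id": exp.cell_table["id"]})
    if exp.size_factors is not None:
        sf["size_factor"] = exp.size_factors
    for name, vals in exp.spike_size_factors.items():
        sf[f"spike_size_factor:{name}"] = vals
    if sf.shape[1] > 1:
        sf.to_csv(directory / "sizefactors.tsv", sep="\t", index=False)
    if exp.log_exprs is not None:
        scipy.io.mmwrite(str(directory / "logexprs.mtx"), np.asarray(exp.log_exprs))


def load_bundle(directory) -> Experiment:
    """Load an Experiment bundle written by :func:`save_bundle`."""
    directory = Path(directory)
    mat, feature_ids, cell_ids = read_counts(directory / "counts.mtx")
    ftab = pd.read_csv(directory / "features.tsv", sep="\t")
    ctab = pd.read_csv(directory / "cells.tsv", sep="\t")
    control_sets = {}
    for col in list(ftab.columns):
        if col.startswith("set:"):
            control_sets[col[4:]] = ftab[col].to_numpy(dtype=bool)
            ftab = ftab.drop(columns=[col])
    exp = Experiment(counts=mat, feature_table=ftab, cell_table=ctab, control_sets=control_sets)
    meta_path = directory / "meta.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        for name, general_use in meta.get("spike_sets", {}).items():
            exp.declare_spike_set(name, general_use)
    sf_path = directory / "sizefactors.tsv"
    if sf_path.exists():
        sf = pd.read_csv(sf_path, sep="\t")
        if "size_factor" in sf.columns:
            exp.size_factors = sf["size_factor"].to_numpy(float)
        for col in sf.columns:
            if col.startswith("spike_size_factor:"):
                exp.spike_size_factors[col.split(":", 1)[1]] = sf[col].to_numpy(float)
    le_path = directory / "logexprs.mtx"
    if le_path.exists():
        exp.log_exprs = np.asarray(sp.csr_matrix(scipy.io.mmread(str(le_path))).todense())
    return exp
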