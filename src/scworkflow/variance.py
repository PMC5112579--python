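"""Variance modelling: mean-variance trend, decomposition and HVG selection.

The variance of each gene's normalized log-expression is split into a
technical component — the value of a smooth mean-variance trend at the
gene's mean — and a biological component, the residual above the trend.
The trend can be fitted to spike-in transcripts (which carry technical
variation only) or, when spike-ins are too few or unevenly distributed, to
the endogenous genes under the assumption that most are not variably
expressed.  Highly variable genes (HVGs) are genes whose biological
component is both statistically significant and large enough to matter: the
default floor of 0.5 on log2 values corresponds to an average difference of
at least 2-fold in true expression between cells.

The module also provides variance-explained diagnostics for technical
factors and removal of nuisance covariates from the expression matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "gene_stats",
    "fit_trend",
    "TrendFit",
    "decompose_variance",
    "select_hvgs",
    "explained_variance",
    "remove_nuisance",
    "design_matrix",
]


def design_matrix(*factors, intercept: bool = True) -> np.ndarray:
    """Build a design matrix from categorical or numeric per-cell factors.

    Categorical factors expand to mean-centred one-hot contrasts (dropping
    one level against the intercept); numeric factors enter as given.
    """
    cols = []
    n = None
    for f in factors:
        f = np.asarray(f)
        n = len(f) if n is None else n
        if len(f) != n:
            raise ValueError("factors must have equal length")
        if f.dtype.kind in "OUSb":
            levels = pd.unique(f)
            if len(levels) < 2:
                raise ValueError("categorical factor must have at least two levels")
            for lev in levels[1:]:
                cols.append((f == lev).astype(float))
        else:
            cols.append(f.astype(float))
    parts = [np.ones(n)] if intercept else []
    parts.extend(cols)
    return np.column_stack(parts)


def gene_stats(log_exprs, design: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Per-gene mean, (design-adjusted) variance, and residual df.

    Without a design this is the sample mean and variance (denominator
    n - 1).  With a design, the variance is the residual mean square from a
    per-gene linear fit, with df = n - rank(design); the reported mean stays
    the plain average of the log-expression values.
    """
    Y = np.asarray(log_exprs, dtype=float)
    n = Y.shape[1]
    means = Y.mean(axis=1)
    if design is None:
        df = n - 1
        if df < 1:
            raise ValueError("need at least two cells")
        total = Y.var(axis=1, ddof=1)
    else:
        X = np.asarray(design, dtype=float)
        if X.shape[0] != n:
            raise ValueError("design rows must match number of cells")
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            raise ValueError("design matrix is rank deficient")
        if n <= rank:
            raise ValueError("more design coefficients than cells")
        Q, _ = np.linalg.qr(X)
        fitted = (Y @ Q) @ Q.T
        df = n - rank
        total = ((Y - fitted) ** 2).sum(axis=1) / df
    return pd.DataFrame({"mean": means, "total": total, "df": df})


@dataclass
class TrendFit:
    """Fitted smooth mean -> variance function.

    Local linear regression with tricube weights over the ``span`` fraction
    of nearest training points.  Fitted values are clamped at zero and the
    trend is constant-extrapolated outside the training mean range, which is
    the safe choice when the training points (e.g. spike-ins) cover the
    abundance range unevenly.
    """

    means: np.ndarray
    variances: np.ndarray
    span: float
    source: str = "endogenous"

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        if self.means.size != self.variances.size:
            raise ValueError("means and variances differ in length")
        if self.means.size < 10:
            raise ValueError("need at least 10 points to fit a trend")
        if not 0 < self.span <= 1:
            raise ValueError("span must lie in (0, 1]")
        order = np.argsort(self.means, kind="stable")
        self._x = self.means[order]
        self._y = self.variances[order]
        self._k = max(2, int(np.ceil(self.span * self._x.size)))

    def __call__(self, at) -> np.ndarray:
        scalar = np.ndim(at) == 0
        at = np.atleast_1d(np.asarray(at, dtype=float))
        q = np.clip(at, self._x[0], self._x[-1])  # constant extrapolation
        out = np.empty(q.size)
        x, y, k = self._x, self._y, self._k
        for i, x0 in enumerate(q):
            d = np.abs(x - x0)
            idx = np.argpartition(d, k - 1)[:k]
            h = d[idx].max()
            if h == 0:
                out[i] = y[idx].mean()
                continue
            w = (1 - (d[idx] / h) ** 3) ** 3
            xs = x[idx] - x0
            swx = np.sum(w * xs)
            swx2 = np.sum(w * xs * xs)
            sw = np.sum(w)
            swy = np.sum(w * y[idx])
            swxy = np.sum(w * xs * y[idx])
            denom = sw * swx2 - swx * swx
            if denom <= np.finfo(float).tiny * max(1.0, sw * swx2):
                out[i] = swy / sw
            else:
                out[i] = (swx2 * swy - swx * swxy) / denom
        result = np.maximum(out, 0.0)
        return float(result[0]) if scalar else result


def fit_trend(means, variances, span: float = 0.3, source: str = "endogenous") -> TrendFit:
    """Fit the mean-variance trend (see :class:`TrendFit`)."""
    return TrendFit(np.asarray(means), np.asarray(variances), span=span, source=source)


def decompose_variance(stats_table: pd.DataFrame, trend: TrendFit) -> pd.DataFrame:
    """Split total variance into technical and biological components.

    tech = trend(mean); bio = total - tech (exactly, by construction).  The
    one-sided p-value tests whether the total variance exceeds the technical
    expectation, treating df * total / tech as chi-square with the residual
    df; FDR is Benjamini-Hochberg across genes.  Genes where the trend is
    non-positive get missing p-values with a warning.
    """
    means = stats_table["mean"].to_numpy(dtype=float)
    total = stats_table["total"].to_numpy(dtype=float)
    df = stats_table["df"].to_numpy(dtype=float)
    tech = np.asarray(trend(means), dtype=float)
    bio = total - tech
    p = np.full(means.size, np.nan)
    ok = tech > 0
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} genes have non-positive technical variance; p set to missing")
    p[ok] = stats.chi2.sf(df[ok] * total[ok] / tech[ok], df[ok])
    fdr = np.full_like(p, np.nan)
    if ok.any():
        fdr[ok] = multipletests(p[ok], method="fdr_bh")[1]
    out = pd.DataFrame(
        {"mean": means, "total": total, "bio": bio, "tech": tech, "p.value": p, "FDR": fdr}
    )
    if "name" in stats_table.columns:
        out.insert(0, "name", stats_table["name"].to_numpy())
    out.index = stats_table.index
    return out


def select_hvgs(table: pd.DataFrame, fdr: float = 0.05, bio_min: float = 0.5) -> pd.DataFrame:
    """Rows with FDR <= ``fdr`` and bio >= ``bio_min``, sorted by bio descending."""
    keep = (table["FDR"] <= fdr) & (table["bio"] >= bio_min)
    keep &= table["FDR"].notna()
    return table.loc[keep].sort_values("bio", ascending=False, kind="stable")


def explained_variance(log_exprs, factor) -> np.ndarray:
    """Percentage of each gene's variance explained by one factor (0-100).

    The factor may be numeric or categorical; the value is 100 x R-squared
    of the per-gene one-factor linear fit.
    """
    Y = np.asarray(log_exprs, dtype=float)
    f = np.asarray(factor)
    if len(f) != Y.shape[1]:
        raise ValueError("factor length must match number of cells")
    X = design_matrix(f)
    if np.linalg.matrix_rank(X) < 2:
        raise ValueError("factor is constant; nothing to explain")
    Q, _ = np.linalg.qr(X)
    fitted = (Y @ Q) @ Q.T
    centred = Y - Y.mean(axis=1, keepdims=True)
    tss = (centred**2).sum(axis=1)
    rss = ((Y - fitted) ** 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(tss > 0, 1.0 - rss / tss, 0.0)
    return 100.0 * np.clip(r2, 0.0, 1.0)


def remove_nuisance(log_exprs, batch=None, covariates=None) -> np.ndarray:
    """Regress nuisance batch/covariate effects out of the expression matrix.

    Fits, per gene, a linear model on intercept + mean-centred batch
    contrasts + covariates and subtracts the fitted nuisance components,
    preserving the intercept (grand mean).  With neither batch nor
    covariates this is the identity.
    """
    Y = np.asarray(log_exprs, dtype=float)
    n = Y.shape[1]
    nuis_cols = []
    if batch is not None:
        b = np.asarray(batch)
        levels = pd.unique(b)
        for lev in levels[1:]:
            col = (b == lev).astype(float)
            nuis_cols.append(col - col.mean())  # centred contrast keeps grand mean
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] == n and cov.shape[1] != n:
            cov = cov.T
        for row in cov:
            nuis_cols.append(row - row.mean())
    if not nuis_cols:
        return Y.copy()
    X = np.column_stack([np.ones(n)] + nuis_cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("confounded design: nuisance terms are collinear")
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    nuisance_fit = X[:, 1:] @ beta[1:]
    return Y - nuisance_fit.T
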