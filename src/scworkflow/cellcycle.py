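"""Pair-sign cell-cycle phase classification.

Training (:func:`sandbag`) finds gene pairs whose within-cell expression
ordering flips between cell-cycle phases: (g1, g2) marks phase P when g1
exceeds g2 in most P cells and falls below it in most cells of every other
phase.  Scoring (:func:`cyclone_scores`) asks, for each test cell, how many
marker pairs show the phase-consistent ordering, and normalizes that raw
proportion against random within-cell shuffles of the participating genes'
expression values.  Because only the relative ordering of expression within
each cell is used, scores are invariant to any monotone per-cell transform.

Pair sets serialize as three-column TSV (phase, gene1, gene2) so externally
trained classifiers can be imported; no pre-trained sets ship with the
package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "MarkerPairSet",
    "sandbag",
    "cyclone_scores",
    "assign_phase",
]

PHASES = ("G1", "S", "G2M")


@dataclass
class MarkerPairSet:
    """Ordered marker gene pairs per cell-cycle phase."""

    pairs: Dict[str, List[Tuple[str, str]]] = field(default_factory=dict)

    def __post_init__(self):
        for phase, plist in self.pairs.items():
            for g1, g2 in plist:
                if g1 == g2:
                    raise ValueError(f"degenerate pair ({g1}, {g2}) in phase {phase}")

    def n_pairs(self) -> Dict[str, int]:
        return {p: len(v) for p, v in self.pairs.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"phase": phase, "gene1": g1, "gene2": g2}
            for phase, plist in self.pairs.items()
            for g1, g2 in plist
        ]
        return pd.DataFrame(rows, columns=["phase", "gene1", "gene2"])

    def save(self, path):
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path) -> "MarkerPairSet":
        table = pd.read_csv(path, sep="\t")
        pairs: Dict[str, List[Tuple[str, str]]] = {}
        for phase, g1, g2 in table[["phase", "gene1", "gene2"]].itertuples(index=False):
            pairs.setdefault(str(phase), []).append((str(g1), str(g2)))
        return cls(pairs)


def sandbag(
    train_exprs,
    genes: Sequence[str],
    phase_labels: Sequence[str],
    frac: float = 0.5,
) -> MarkerPairSet:
    """Mine phase-marker gene pairs from labelled training data.

    A pair (g1, g2) is a marker for phase P when expr(g1) > expr(g2) in at
    least ``frac`` of the P cells and expr(g1) < expr(g2) in at least
    ``frac`` of the cells of every other phase.  Ties count for neither
    direction.  Raising ``frac`` can only shrink the marker set.
    """
    X = np.asarray(train_exprs, dtype=float)
    genes = np.asarray(genes)
    labels = np.asarray(phase_labels)
    if X.shape != (len(genes), len(labels)):
        raise ValueError("expression matrix must be genes x cells")
    phases = [p for p in dict.fromkeys(labels)]
    if len(phases) < 2 or any((labels == p).sum() < 2 for p in phases):
        raise ValueError("need at least two phases with at least two cells each")

    ngenes = len(genes)
    # proportion of cells in each phase with expr(g1) > expr(g2)
    gt = {}
    for p in phases:
        sub = X[:, labels == p]
        # chunk over g1 to bound memory on larger gene sets
        mat = np.empty((ngenes, ngenes))
        step = max(1, int(2e7 // (ngenes * sub.shape[1] + 1)))
        for start in range(0, ngenes, step):
            stop = min(ngenes, start + step)
            mat[start:stop] = (sub[start:stop, None, :] > sub[None, :, :]).mean(axis=2)
        gt[p] = mat

    pairs: Dict[str, List[Tuple[str, str]]] = {}
    for p in phases:
        ok = gt[p] >= frac
        for q in phases:
            if q == p:
                continue
            # expr(g1) < expr(g2) in phase q  <=>  gt[q].T >= frac at (g1, g2)
            ok &= gt[q].T >= frac
        np.fill_diagonal(ok, False)
        i1, i2 = np.nonzero(ok)
        pairs[p] = [(str(genes[a]), str(genes[b])) for a, b in zip(i1, i2)]
    return MarkerPairSet(pairs)


def cyclone_scores(
    test_exprs,
    genes: Sequence[str],
    pairs: MarkerPairSet,
    iterations: int = 1000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Randomization-normalized phase scores for each test cell.

    For each phase, the raw statistic of a cell is the proportion of marker
    pairs (restricted to those whose genes are present in the test data;
    skipped pairs are counted in the ``n_skipped_pairs`` attribute) with
    expr(g1) > expr(g2), among pairs with unequal expression.  The score is
    the fraction of ``iterations`` random within-cell shuffles of the
    participating genes' values whose raw statistic falls below the observed
    one, counting ties as half.  Scores lie in [0, 1] and are reproducible
    given a seed.
    """
    X = np.asarray(test_exprs, dtype=float)
    genes = list(map(str, genes))
    if rng is None:
        rng = np.random.default_rng(seed)
    index = {}
    for i, g in enumerate(genes):
        index.setdefault(g, i)  # first match on duplicated names

    ncells = X.shape[1]
    scores = {}
    skipped = {}
    for phase, plist in pairs.pairs.items():
        usable = [(index[g1], index[g2]) for g1, g2 in plist if g1 in index and g2 in index]
        skipped[phase] = len(plist) - len(usable)
        if not usable:
            raise ValueError(f"no usable marker pairs for phase {phase!r} after id matching")
        i1 = np.array([a for a, _ in usable])
        i2 = np.array([b for _, b in usable])
        participating = np.unique(np.concatenate([i1, i2]))
        remap = np.full(X.shape[0], -1)
        remap[participating] = np.arange(participating.size)
        j1, j2 = remap[i1], remap[i2]

        phase_scores = np.full(ncells, np.nan)
        for c in range(ncells):
            v = X[participating, c]
            d = v[j1] - v[j2]
            informative = np.count_nonzero(d)
            if informative == 0:
                continue
            robs = np.count_nonzero(d > 0) / informative
            shuffled = rng.permuted(np.broadcast_to(v, (iterations, v.size)), axis=1)
            D = shuffled[:, j1] - shuffled[:, j2]
            pos = (D > 0).sum(axis=1)
            nz = (D != 0).sum(axis=1)
            with np.errstate(invalid="ignore"):
                rnull = np.where(nz > 0, pos / np.maximum(nz, 1), np.nan)
            valid = ~np.isnan(rnull)
            if not valid.any():
                continue
            below = (rnull[valid] < robs).mean()
            tied = (rnull[valid] == robs).mean()
            phase_scores[c] = below + 0.5 * tied
        scores[phase] = phase_scores

    result = pd.DataFrame(scores)
    result.attrs["n_skipped_pairs"] = skipped
    if {"G1", "G2M"} <= set(result.columns):
        result["phase"] = assign_phase(result)
    return result


def assign_phase(scores: pd.DataFrame) -> np.ndarray:
    """Assign each cell to G1, S or G2M from its G1/G2M scores.

    G1 when the G1 score is above 0.5 and at least the G2/M score; G2M when
    the G2/M score is above 0.5 and exceeds the G1 score; S when neither
    score is above 0.5.  Cells with missing scores get a missing label.
    """
    g1 = scores["G1"].to_numpy(dtype=float)
    g2m = scores["G2M"].to_numpy(dtype=float)
    out = np.full(len(scores), "S", dtype=object)
    out[(g1 > 0.5) & (g1 >= g2m)] = "G1"
    out[(g2m > 0.5) & (g2m > g1)] = "G2M"
    out[np.isnan(g1) | np.isnan(g2m)] = None
    return out
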