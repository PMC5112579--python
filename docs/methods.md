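# Methods

This note documents the statistical procedures implemented in
`scworkflow`, the defaults and why they were chosen, what the synthetic
data generator does and does not emulate, and the numerical decisions that
matter for reproducing results.

## Data model

An `Experiment` holds a non-negative feature-by-cell count matrix (stored
sparse), per-feature and per-cell annotation tables, named control sets
(boolean feature masks, e.g. `ERCC`, `Mt`), spike-in declarations with a
`general_use` flag, per-cell size factors (a general slot plus one slot per
spike-in set), and an optional log-expression matrix. Row order is
authoritative for feature identity; names may repeat (public symbol-keyed
datasets do), and a warning is emitted. All slots are sliced together on
subsetting; size factors are carried as-is when cells are dropped and are
re-centred to mean 1 only when (re)computed, so filtering does not silently
rescale expression.

## Quality control

Library size (total counts over all features, spike-ins included),
expressed-feature count, and the percentage of counts in each control set
are the metrics. Outliers are values more than `nmads` (default 3) median
absolute deviations from the median, with MAD scaled by 1.4826 so it
estimates a standard deviation under normality. Library sizes and feature
counts are tested on the natural-log scale (the flagged set is provably
independent of the log base, since any base change is a positive affine map
of the transformed values); zero values map to -inf and are always caught
by lower-side tests. Control percentages are tested on the raw scale,
upper side. The union of filters is removed; removing more than 10% of
cells triggers a warning since it can indicate a global quality problem.
The QC PCA standardizes each metric to unit variance before projection;
coordinates are deterministic with the sign fixed so each component's
largest loading is positive.

## Gene filtering

The mean-based filter keeps genes with mean raw count ≥ threshold
(inclusive). A threshold of 1 suits read counts; UMI data needs a lower
threshold (e.g. 0.2) because library sizes are much smaller. The
"at least n cells" filter is also provided but depends strongly on n and
can erase rare subpopulations, so the mean filter is preferred. Means are
computed on raw counts over the current (post-QC) cell set.

## Normalization

**Deconvolution.** Within each cluster of cells: each cell is scaled to
unit library size and the reference pseudo-cell is the per-gene average of
the scaled cells times the mean library size. Cells are placed on a ring —
sorted by library size, odd ranks ascending then even ranks descending, so
every window mixes small and large libraries — and for each pool size
(default 20, 40, 60, 80, clamped to the available cells with a warning)
and each ring window, the pool factor is the median over genes of pooled
scaled counts divided by the reference. Genes whose reference average
falls below `min_mean` (default 0.1) are excluded from the medians, as are
all-zero genes. The linear system "sum of member factors = pool factor" is
augmented with per-cell library-size equations at relative weight 1e-6 to
make it full rank — in the no-DE case any positive weight yields the exact
solution — and solved by least squares (dense QR up to 1200 cells, sparse
LSQR above). Solved coefficients are multiplied by library size; a
non-positive result raises an error naming the offending cells. With
multiple clusters, each cluster's factors are rescaled by the median ratio
of its pseudo-cell to a reference cluster (the one with most non-zero
genes), then everything is centred to mean 1. Whether centring happens
before or after rescaling does not affect ratios; we centre last.

**Pre-clustering** (`quick_cluster`) uses the distance
sqrt((1 - ρ)/2) with ρ the Spearman correlation between cell profiles,
average linkage, and the lowest cut at which every cluster still has
`min_size` (default 200) cells. Rank-based distances are robust to
normalization errors; the cut rule guarantees every cluster is large
enough for the biggest pool.

**Spike-in factors** are each cell's total count over a spike-in set,
centred to mean 1; every cell must have at least one spike count. With
`general_use=True` they are applied to all features — appropriate when
total-RNA differences are biology to be preserved rather than bias to be
removed; otherwise they normalize only the spike-in rows while the
deconvolution factors handle endogenous genes.

**Log-expression** is log2(count / factor + 1). Zero counts map to
exactly 0 for any factor; the prior count of 1 avoids undefined values and
stabilises variances.

## Cell-cycle phase classification

Training (`sandbag`): (g1, g2) is a marker pair for phase P when
expr(g1) > expr(g2) in at least `frac` (default 0.5) of P cells and
expr(g1) < expr(g2) in at least `frac` of the cells of every other phase.
Ties count for neither side — a deliberate choice documented because UMI
data is tie-rich. Scoring (`cyclone_scores`): per cell and phase, the raw
statistic is the proportion of non-tied marker pairs with
expr(g1) > expr(g2); the score is the fraction of `iterations` (default
1000) random within-cell shuffles of the participating genes' values whose
statistic falls below the observed one, ties counted half. Only the genes
participating in that phase's pairs are shuffled: the randomization then
asks exactly "is this ordering pattern surprising for these genes in this
cell", and the choice is validated by ≥90% held-out label recovery on
synthetic three-phase data. Scores depend only on within-cell orderings,
so any monotone per-cell transformation (and any normalization that
preserves ranks) leaves them unchanged. Assignment: G1 if the G1 score is
above 0.5 and at least the G2/M score (equality resolved in favour of G1 —
a measure-zero event under continuous scores); G2M if its score is above
0.5 and exceeds G1; otherwise S. Pair sets serialize as TSV
(phase, gene1, gene2) so externally trained classifiers can be imported;
no pre-trained sets ship with the package, and unresolvable pairs are
skipped with their count reported.

## Variance decomposition and HVGs

Per-gene means and variances come from the log-expression matrix; with a
design matrix the variance is the residual mean square (df = n - rank),
which removes nuisance factors such as sex or phase scores from the
variance estimate. The mean-variance trend is a local linear regression
with tricube weights over the `span` fraction of nearest points, fitted to
raw variances, clamped at zero, and constant-extrapolated outside the
training range — the safe behaviour when spike-ins cover abundances
unevenly. Robustness iterations are off; `span` is a required, logged
parameter (0.2 is a good default for dense endogenous fits, 0.4 for sparse
spike-in fits). The technical component is the trend at the gene's mean;
bio = total - tech exactly.

Significance: the procedure reports a p-value per gene but no closed-form
test is canonical; we treat df·total/tech as chi-square with the residual
df (upper tail), which is exact when the true variance equals the trend
and log-expression is approximately normal, and is validated by null
simulations (KS-uniform p-values, mean bio within 2 SE of zero).
Benjamini-Hochberg is the only multiple-testing correction used anywhere
in the package. HVGs are genes with FDR ≤ 0.05 and bio ≥ 0.5, ranked by
bio; on the log2 scale bio = 0.5 means the RMS difference in true
expression between two cells is sqrt(2·0.5) = 1, i.e. an average 2-fold
difference.

Diagnostics: `explained_variance` reports 100·R² of a one-factor fit per
gene; `remove_nuisance` regresses out batch (mean-centred contrasts, so
the grand mean is preserved) and/or numeric covariates.

## Correlated gene pairs

Spearman's ρ is the Pearson correlation of tie-averaged ranks. The null
distribution is ρ between a fixed rank vector and uniformly random
permutations of it; because rank patterns are exchangeable under
independence, one null sample of size N is shared by all pairs with the
same number of cells. The two-sided p-value is min(1, 2(k+1)/(N+1)) with
k the number of null draws at least as extreme as the observed ρ in its
direction; the add-one estimator floors p at 2/(N+1), which is
1.999998e-06 at the default N = 10⁶. With a design matrix, correlations
are computed on ranks of per-gene residuals; an intercept-only design
reproduces the design-free result exactly. Testing is restricted to a
caller-supplied subset (typically the HVGs): all-pairs testing over the
transcriptome is deliberately out of scope, both for time and for the
multiplicity cost.

Significant pairs (BH FDR ≤ 0.05) are edges of an undirected graph.
Highly connected subgraphs — edge connectivity > n/2; a connected 2-node
graph qualifies — are extracted by recursive minimum-cut splitting.
The global minimum cut is found deterministically: the source is the
lexicographically smallest node and targets are scanned in sorted order
until an s-t cut achieves the global edge connectivity, so ties between
equal cuts are broken reproducibly. Singletons are discarded; clusters
are returned largest first.

## Clustering and marker detection

Cells are clustered with Ward's criterion on Euclidean distances between
log-expression profiles over a chosen gene subset (scipy's `ward`, i.e.
the Ward.D2 update on unsquared distances). Clusters come from a static
cut (by count or height); clusters below `min_size` are merged into the
nearest cluster by centroid distance, and labels are numbered by
decreasing size. A dynamic, shape-aware tree cut is a cited external
method and is intentionally not reimplemented — cluster definitions here
only feed marker ranking.

Marker detection tests each gene between the target cluster and every
other cluster separately. The `welch` engine is a Welch t-test on
log-expression (distribution-free of count-model assumptions). The
`nb_lrt` engine fits, per gene, a negative-binomial GLM to the raw counts
of the two clusters with log size factors as offsets and optional blocking
columns; the per-gene dispersion is estimated once on the full one-hot
cluster design by maximising the adjusted profile likelihood
(llf - ½ log det XᵀWX) over a fixed grid (1e-4 to 20, 19 points), and each
contrast is a 1-df likelihood-ratio test. This is a deliberately
simplified NB engine — no empirical-Bayes dispersion shrinkage — so its
p-values and dispersion summaries will differ from dedicated count-model
packages; directions and rankings agree on planted-DE simulations. Log
fold changes are target minus comparison on the log2 scale. Results
aggregate by ranking each comparison's p-values (ties broken by first
occurrence) and taking each gene's minimum rank ("Top"); retaining
Top ≤ t yields the t strongest candidates from every comparison. Because
clusters are defined from the same data, these p-values rank genes; they
are not calibrated significance measures. For heatmaps the package
provides the per-gene mean-centred matrix; rendering is left to standard
tools.

## Synthetic data

`simulate_counts` draws NB counts with variance μ + φμ² (default
φ = 0.1). Gene means are log-normal on the log2 scale (default mean 2,
sd 1.5); per-cell capture factors are log-normal with CV `libsize_cv`
(default 0.3); cluster RNA content spreads geometrically up to
`rna_content_fold`. Endogenous means scale with capture × content and any
planted cluster log-fold change; spike-ins have fixed concentrations
(scaled so they are `spike_fraction`, default 5%, of the endogenous total)
and scale with capture only. With `library_quantified=True` the cDNA of
each cell is notionally equalized before sequencing: expected totals are
capture × baseline and endogenous/spike molecules compete for the depth,
so higher RNA content lowers relative spike-in coverage — this is the
regime in which spike-in and deconvolution size factors become negatively
correlated, and the divergence tests use it with libsize_cv = 0.1 and
spike_fraction = 0.1, matching a plate-based protocol with library
quantification and typical spike-in content. Optionally, extra log-normal
biological variability is planted in a subset of genes (true HVGs).
`simulate_cycle` builds three-phase expression with phase genes elevated
by a large effect in their own phase on strictly ordered baselines;
unmodulated genes are placed at the highest baselines so the noiseless
pair-mining combinatorics are exact (at least n_phase_genes² marker pairs
per phase; requires n_genes ≥ 4·n_phase_genes). Everything is reproducible
from the seed, and the full truth (factors, labels, DE genes, dispersions)
is returned and serialized.

What the generator does not emulate: amplification and gene-length
biases, droplet ambient RNA and doublets, batch-specific composition
shifts, zero inflation beyond what NB sampling produces, and realistic
gene-gene correlation structure outside the planted clusters and HVGs.
Passing tests therefore demonstrate correctness of the algorithms under
the stated noise model, not robustness to every artefact of real data.

## Problem sizes and numerical choices

The test suite runs on deliberately small problems (tens to a few hundred
cells, hundreds of genes) chosen so each check isolates one property; the
permutation-floor check uses the full default of 10⁶ iterations because
the floor is exact, not asymptotic. The null-calibration checks average
over replicates where a shared Monte-Carlo null would otherwise add
common noise beyond binomial scatter. Least-squares deconvolution switches
from dense QR to sparse LSQR above 1200 cells; tolerances are 1e-12.
Degenerate inputs fail loudly: empty cell sets, all-false masks,
rank-deficient or confounded designs, zero spike totals, missing metadata
columns and missing size factors all raise immediately rather than
propagating NaNs.

## Known limitations

Exact numerical agreement with reference implementations of the same
workflow is not promised for quantities that depend on smoother internals
(loess details) or dispersion machinery (empirical-Bayes shrinkage):
HVG counts, significant-pair counts and marker tables can differ in detail
while agreeing in ranking behaviour. The cell-cycle classifier needs a
user-supplied training set or imported pair list. The HCS min-cut is
exact but O(n·maxflow) per split, fine for correlated-HVG graphs
(hundreds of nodes), not for transcriptome-scale graphs.
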