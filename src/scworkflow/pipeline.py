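"""Config-driven pipeline orchestration.

Runs the stages qc -> cellcycle -> filter -> normalize -> hvg -> correlate ->
cluster -> markers in fixed order on a count bundle (or a simulation spec),
writing each stage's outputs, a resumable on-disk state bundle, and a log
line per stage recording parameters, seeds and the resulting dimensions.
Stages not named in the config are skipped; a stage whose prerequisites were
skipped raises a stage-order error.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict

import numpy as np
import pandas as pd
import yaml

from . import (
    MarkerPairSet,
    apply_cell_filters,
    build_gene_graph,
    compute_qc_metrics,
    compute_spike_factors,
    compute_sum_factors,
    correlate_pairs,
    cut_clusters,
    cyclone_scores,
    decompose_variance,
    drop_feature_set,
    fit_trend,
    gene_stats,
    hcs_clusters,
    is_outlier,
    load_bundle,
    mean_filter,
    ncells_filter,
    normalize_log,
    pairwise_de,
    quick_cluster,
    rank_markers,
    save_bundle,
    select_hvgs,
    simulate_counts,
    ward_tree,
    write_table,
)
from .variance import design_matrix

__all__ = ["run_pipeline", "STAGE_ORDER"]

STAGE_ORDER = ["qc", "cellcycle", "filter", "normalize", "hvg", "correlate", "cluster", "markers"]

log = logging.getLogger("scworkflow.pipeline")


def _load_config(config) -> Dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def run_pipeline(config, outdir=None) -> Path:
    """Execute the configured stages; return the artifact directory.

    The config (mapping or YAML path) names an ``input`` bundle or a
    ``simulate`` parameter block, an ``outdir``, and one block per stage to
    run.  Stage outputs land in ``<outdir>/<stage>/``; the evolving
    experiment state is saved under ``<outdir>/state`` after every stage so
    runs can resume.  Reruns with the same config and seeds are identical.
    """
    cfg = _load_config(config)
    outdir = Path(outdir or cfg.get("outdir", "scworkflow_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    if not log.handlers:
        logging.basicConfig(level=logging.INFO, format="%(message)s")
    fh = logging.FileHandler(outdir / "pipeline.log")
    log.addHandler(fh)

    try:
        exp, context = _load_input(cfg, outdir)
        log.info("input: dims=%s", exp.dims)
        requested = [s for s in STAGE_ORDER if s in cfg]
        unknown = [s for s in cfg if s not in STAGE_ORDER + ["input", "simulate", "outdir"]]
        if unknown:
            raise ValueError(f"unknown config sections: {unknown}")
        for stage in requested:
            stage_dir = outdir / stage
            stage_dir.mkdir(exist_ok=True)
            exp = _STAGES[stage](exp, cfg[stage] or {}, stage_dir, context)
            save_bundle(exp, outdir / "state")
            log.info("stage %s done: dims=%s params=%s", stage, exp.dims, cfg[stage])
        (outdir / "completed.json").write_text(json.dumps({"stages": requested}))
    finally:
        log.removeHandler(fh)
        fh.close()
    return outdir


def _load_input(cfg, outdir):
    context: Dict = {}
    if "simulate" in cfg:
        params = dict(cfg["simulate"])
        if "seed" not in params:
            raise ValueError("simulation requires an explicit seed")
        exp, truth = simulate_counts(**params)
        sim_dir = outdir / "simulate"
        sim_dir.mkdir(exist_ok=True)
        for name, frame in truth.to_frames().items():
            write_table(frame, sim_dir / f"truth_{name}.tsv")
        save_bundle(exp, sim_dir / "bundle")
        context["truth"] = truth
        log.info("simulated experiment: dims=%s seed=%s", exp.dims, params["seed"])
    elif "input" in cfg:
        exp = load_bundle(cfg["input"])
    else:
        raise ValueError("config must provide 'input' or 'simulate'")
    return exp, context


def _stage_qc(exp, params, stage_dir, context):
    nmads = params.get("nmads", 3)
    exp = compute_qc_metrics(exp)
    masks = {}
    filters = params.get("filters", ["libsize", "features"])
    if "libsize" in filters:
        masks["ByLibSize"] = is_outlier(exp.cell_column("total_counts"), nmads, "lower", log=True)
    if "features" in filters:
        masks["ByFeature"] = is_outlier(exp.cell_column("total_features"), nmads, "lower", log=True)
    if "mito" in filters:
        col = f"pct_counts_{params['mito_set']}"
        masks["ByMito"] = is_outlier(exp.cell_column(col), nmads, "higher")
    if "spike" in filters:
        col = f"pct_counts_{params['spike_set']}"
        masks["BySpike"] = is_outlier(exp.cell_column(col), nmads, "higher")
    exp, summary = apply_cell_filters(exp, masks)
    write_table(summary.to_frame(), stage_dir / "filter_summary.tsv", index=True)
    return exp


def _stage_cellcycle(exp, params, stage_dir, context):
    if exp.log_exprs is None:
        # phase scoring is rank-based within cells, so raw counts are usable
        values = exp.dense_counts().astype(float)
    else:
        values = exp.log_exprs
    pairs = MarkerPairSet.load(params["pairs"])
    scores = cyclone_scores(
        values,
        exp.feature_ids,
        pairs,
        iterations=params.get("iterations", 1000),
        seed=params.get("seed"),
    )
    write_table(scores, stage_dir / "phase_scores.tsv")
    for col in ("G1", "S", "G2M"):
        if col in scores:
            exp.cell_table[f"score_{col}"] = scores[col].to_numpy()
    exp.cell_table["phase"] = scores["phase"].to_numpy()
    subset_phase = params.get("subset_phase")
    if subset_phase:
        exp = exp.subset(cell_mask=exp.cell_table["phase"].to_numpy() == subset_phase)
    return exp


def _stage_filter(exp, params, stage_dir, context):
    for set_name in params.get("drop_sets", []):
        exp = drop_feature_set(exp, set_name)
    keep = np.ones(exp.n_features, dtype=bool)
    if "min_mean" in params:
        keep &= mean_filter(exp, params["min_mean"])
    if "min_cells" in params:
        keep &= ncells_filter(exp, params["min_cells"])
    return exp.subset(feature_mask=keep)


def _stage_normalize(exp, params, stage_dir, context):
    sizes = params.get("sizes", [20, 40, 60, 80])
    clusters = None
    if params.get("quick_cluster"):
        clusters = quick_cluster(exp.counts[exp.endogenous_mask], min_size=params.get("min_cluster_size", 200))
    exp.size_factors = compute_sum_factors(
        exp.counts[exp.endogenous_mask], sizes=sizes, clusters=clusters
    )
    spike_set = params.get("spike_set")
    if spike_set:
        compute_spike_factors(exp, spike_set, params.get("spike_general_use", False))
    exp = normalize_log(exp, pseudocount=params.get("pseudocount", 1), base=params.get("base", 2))
    sf = pd.DataFrame({"id": exp.cell_table["id"], "size_factor": exp.size_factors})
    write_table(sf, stage_dir / "sizefactors.tsv")
    return exp


def _require_log_exprs(exp, stage):
    if exp.log_exprs is None:
        raise RuntimeError(f"stage order violation: {stage!r} requires 'normalize' to run first")


def _stage_hvg(exp, params, stage_dir, context):
    _require_log_exprs(exp, "hvg")
    design = None
    if params.get("design"):
        design = design_matrix(*[exp.cell_column(c) for c in params["design"]])
    stats = gene_stats(exp.log_exprs, design=design)
    stats["name"] = exp.feature_ids
    use_spikes = params.get("use_spikes", False)
    train = exp.spike_mask() if use_spikes else exp.endogenous_mask
    trend = fit_trend(
        stats.loc[train, "mean"],
        stats.loc[train, "total"],
        span=params.get("span", 0.3),
        source="spikes" if use_spikes else "endogenous",
    )
    table = decompose_variance(stats, trend)
    endo = table.loc[np.asarray(exp.endogenous_mask)]
    hvgs = select_hvgs(endo, fdr=params.get("fdr", 0.05), bio_min=params.get("bio_min", 0.5))
    cols = ["name", "mean", "total", "bio", "tech", "p.value", "FDR"]
    write_table(hvgs[cols], stage_dir / "hvg.tsv")
    context["hvgs"] = hvgs["name"].tolist()
    return exp


def _stage_correlate(exp, params, stage_dir, context):
    _require_log_exprs(exp, "correlate")
    if "hvgs" not in context:
        raise RuntimeError("stage order violation: 'correlate' requires 'hvg' to run first")
    design = None
    if params.get("design"):
        design = design_matrix(*[exp.cell_column(c) for c in params["design"]])
    table = correlate_pairs(
        exp.log_exprs,
        exp.feature_ids,
        subset_genes=context["hvgs"],
        design=design,
        iterations=params.get("iterations", 1_000_000),
        seed=params.get("seed"),
    )
    write_table(table, stage_dir / "correlations.tsv")
    graph = build_gene_graph(table, fdr=params.get("fdr", 0.05))
    clusters = hcs_clusters(graph)
    rows = [{"cluster": i + 1, "gene": g} for i, cl in enumerate(clusters) for g in cl]
    write_table(pd.DataFrame(rows, columns=["cluster", "gene"]), stage_dir / "genesets.tsv")
    context["correlated_genes"] = sorted(graph.nodes())
    return exp


def _stage_cluster(exp, params, stage_dir, context):
    _require_log_exprs(exp, "cluster")
    gene_names = context.get("correlated_genes") or context.get("hvgs")
    if not gene_names:
        raise RuntimeError("stage order violation: 'cluster' requires 'hvg'/'correlate' results")
    mask = np.isin(exp.feature_ids, gene_names)
    tree = ward_tree(exp.log_exprs, genes=mask)
    labels = cut_clusters(
        tree,
        k=params.get("k"),
        height=params.get("height"),
        min_size=params.get("min_size", 1),
    )
    exp.cell_table["cluster"] = labels
    write_table(
        pd.DataFrame({"id": exp.cell_table["id"], "cluster": labels}),
        stage_dir / "clusters.tsv",
    )
    return exp


def _stage_markers(exp, params, stage_dir, context):
    if "cluster" not in exp.cell_table.columns:
        raise RuntimeError("stage order violation: 'markers' requires 'cluster' to run first")
    labels = exp.cell_table["cluster"].to_numpy()
    block = exp.cell_column(params["block"]) if params.get("block") else None
    target = params.get("target", 1)
    res = pairwise_de(exp, labels, target, engine=params.get("engine", "welch"), design_extra=block)
    comparisons = {k: v for k, v in res.items() if k.startswith("vs.")}
    table = rank_markers(
        {k: v["p.value"] for k, v in comparisons.items()},
        {k: v["logFC"] for k, v in comparisons.items()},
        exp.feature_ids,
        top=params.get("top"),
    )
    write_table(table, stage_dir / f"markers_{target}.tsv")
    return exp


_STAGES = {
    "qc": _stage_qc,
    "cellcycle": _stage_cellcycle,
    "filter": _stage_filter,
    "normalize": _stage_normalize,
    "hvg": _stage_hvg,
    "correlate": _stage_correlate,
    "cluster": _stage_cluster,
    "markers": _stage_markers,
}
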