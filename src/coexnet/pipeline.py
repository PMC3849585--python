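"""End-to-end pipeline: correlate, cluster, calibrate, enrich, collapse.

The pipeline runs a fixed stage order on a normalized expression matrix
(read from disk or generated synthetically):

1. sample-to-sample correlation graph (default r >= 0.90) + MCL clusters;
2. probeset edge list saved at the save threshold (default r >= 0.70);
3. probeset coexpression graph (default r >= 0.75);
4. MCL clustering, clusters numbered when larger than 6 nodes;
5. pseudo-probeset null simulation at the graph threshold;
6. per-cluster term enrichment (when an annotation map is supplied);
7. collapsed cluster diagram (clusters larger than 10 nodes);
8. machine-readable ``summary.json``.

Every stage logs its parameters and seed; deterministic stages are
bit-identical across reruns with the same config and seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import yaml

from coexnet import correlation, enrichment, expression, mcl, network, null_model, synthetic

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "thresholds": {"save": 0.70, "gene_graph": 0.75, "sample_graph": 0.90},
    "mcl": {"inflation": 2.2, "min_numbered_size": 6, "prune_threshold": 1e-5},
    "null_model": {"n_correlations": 1_000_000, "threshold": 0.75},
    "enrichment": {"alpha": 0.05, "top_k": 10},
    "collapse": {"min_cluster_size": 10},
    "correlation": {"chunk_size": 2000},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path) -> dict:
    with open(path, "rt", encoding="utf-8") as fh:
        return _merge(DEFAULT_CONFIG, yaml.safe_load(fh) or {})


def validate_config(config: dict) -> None:
    th = config["thresholds"]
    if th["gene_graph"] < th["save"]:
        raise ValueError(
            f"gene graph threshold {th['gene_graph']} is below the save "
            f"threshold {th['save']}; edges below the save threshold are never stored"
        )
    if "input" not in config and "synthetic" not in config:
        raise ValueError("config must provide an 'input' or a 'synthetic' section")


def run_pipeline(config: dict, out_dir, seed: int = 0) -> dict:
    """Run the full analysis; artifacts land in ``out_dir``.

    ``config`` is merged over :data:`DEFAULT_CONFIG`; it must contain either
    an ``input`` section (``expression_path`` plus optional ``dialect``,
    ``transform``, ``annotation_path``, ``term_gene_path``) or a
    ``synthetic`` section (keyword arguments of
    :func:`coexnet.synthetic.generate_atlas`; the atlas seed derives from
    ``seed`` unless given explicitly).  Returns the summary dictionary that
    is also written to ``summary.json``.
    """
    config = _merge(DEFAULT_CONFIG, config)
    validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    th = config["thresholds"]
    logger.info("pipeline start: seed=%d thresholds=%s", seed, th)

    truth = None
    annotation_map = None
    if "synthetic" in config:
        syn = dict(config["synthetic"])
        syn.setdefault("seed", seed)
        term_rate = syn.pop("background_term_rate", 0.1)
        matrix, annotations, truth = synthetic.generate_atlas(**syn)
        expression.write_expression_file(matrix, out / "atlas.expression")
        expression.write_annotation_file(annotations, out / "samples.tsv")
        truth.to_json(out / "truth.json")
        annotation_map = synthetic.generate_term_annotation(
            truth, background_term_rate=term_rate, seed=seed + 1
        )
        logger.info(
            "generated synthetic atlas: %d probesets x %d samples (seed=%d)",
            matrix.n_probesets, matrix.n_samples, syn["seed"],
        )
    else:
        inp = config["input"]
        matrix = expression.read_expression_file(
            inp["expression_path"],
            dialect=inp.get("dialect", "expression"),
            transform=inp.get("transform"),
        )
        annotations = (
            expression.read_annotation_file(inp["annotation_path"])
            if inp.get("annotation_path") else None
        )
        if inp.get("term_gene_path"):
            annotation_map = enrichment.read_annotation_map(
                inp["term_gene_path"], inp.get("term_name_path")
            )

    chunk = config["correlation"]["chunk_size"]
    mcl_cfg = config["mcl"]
    params = mcl.MclParams(
        inflation=mcl_cfg["inflation"], prune_threshold=mcl_cfg["prune_threshold"]
    )

    # stage 1: sample-to-sample graph and clusters
    sample_edges = correlation.pairwise_correlations(
        matrix, axis="samples", save_threshold=th["sample_graph"], chunk_size=chunk
    )
    sample_graph = network.build_graph(sample_edges, th["sample_graph"])
    logger.info(
        "sample graph at r >= %.2f: %d nodes, %d edges",
        th["sample_graph"], sample_graph.number_of_nodes(), sample_graph.number_of_edges(),
    )
    sample_clusters = None
    if sample_graph.number_of_nodes():
        sample_clusters = mcl.run_mcl(sample_graph, params)
        sample_clusters = mcl.number_clusters(sample_clusters.raw_clusters, min_numbered_size=0)
        mcl.write_cluster_table(sample_clusters, out / "sample_clusters.tsv")

    # stage 2: saved probeset edge list
    edges = correlation.pairwise_correlations(
        matrix, axis="probesets", save_threshold=th["save"], chunk_size=chunk
    )
    correlation.write_pearson_file(edges, out / "edges.pearson")
    logger.info("saved %d probeset pairs at r >= %.2f", len(edges), th["save"])

    # stage 3-4: probeset graph and MCL clusters
    graph = network.build_graph(edges, th["gene_graph"])
    logger.info(
        "gene graph at r >= %.2f: %d nodes, %d edges",
        th["gene_graph"], graph.number_of_nodes(), graph.number_of_edges(),
    )
    symbol_of = dict(zip(matrix.probeset_ids, matrix.gene_symbols))
    clusters = None
    if graph.number_of_nodes():
        clusters = mcl.run_mcl(graph, params)
        clusters = mcl.number_clusters(
            clusters.raw_clusters, min_numbered_size=mcl_cfg["min_numbered_size"]
        )
        mcl.write_cluster_table(clusters, out / "clusters.tsv", gene_symbol_of=symbol_of)
        network.export_graph(graph, out / "graph.graphml", format="graphml")

    # stage 5: pseudo-probeset null
    null_cfg = config["null_model"]
    null = null_model.simulate_null_tail(
        matrix,
        n_correlations=null_cfg["n_correlations"],
        threshold=null_cfg["threshold"],
        seed=seed,
        observed_chunk_size=chunk,
    )
    null.to_json(out / "null_report.json")
    logger.info(
        "null at r >= %.2f: simulated tail %.3g, observed tail %.3g (seed=%d)",
        null.threshold, null.simulated_tail_fraction, null.observed_tail_fraction, seed,
    )

    # stage 6: enrichment
    enrichment_table = None
    if annotation_map is not None and clusters is not None and clusters.n_numbered:
        enr = config["enrichment"]
        enrichment_table = enrichment.enrich_clusters(
            clusters, annotation_map,
            alpha=enr["alpha"], top_k=enr["top_k"],
            gene_of_probeset=symbol_of if any(matrix.gene_symbols) else None,
        )
        enrichment.write_enrichment_table(enrichment_table, out / "enrichment.tsv")

    # stage 7: collapsed cluster diagram
    collapsed = None
    if clusters is not None:
        collapsed = network.collapse_clusters(
            graph, clusters, min_cluster_size=config["collapse"]["min_cluster_size"]
        )
        network.export_graph(collapsed.to_networkx(), out / "collapsed.graphml")

    summary = {
        "seed": seed,
        "thresholds": th,
        "n_probesets": matrix.n_probesets,
        "n_samples": matrix.n_samples,
        "sample_graph": {
            "nodes": sample_graph.number_of_nodes(),
            "edges": sample_graph.number_of_edges(),
            "clusters": sample_clusters.n_numbered if sample_clusters else 0,
        },
        "gene_graph": {
            "nodes": graph.number_of_nodes(),
            "edges": graph.number_of_edges(),
            "numbered_clusters": clusters.n_numbered if clusters else 0,
        },
        "null_model": {
            "n_simulated": null.n_simulated,
            "threshold": null.threshold,
            "simulated_tail_fraction": null.simulated_tail_fraction,
            "observed_tail_fraction": null.observed_tail_fraction,
            "expected_chance_pairs": null.expected_chance_pairs,
        },
        "enrichment_rows": int(len(enrichment_table)) if enrichment_table is not None else 0,
        "collapsed": {
            "clusters": len(collapsed.cluster_sizes) if collapsed else 0,
            "edges": len(collapsed.cluster_edges) if collapsed else 0,
        },
    }
    with open(out / "summary.json", "wt", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %s", out / "summary.json")
    return summary
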