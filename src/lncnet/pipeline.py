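"""End-to-end orchestration: preprocessing through network export.

Stage order follows the study: presence filter + quantile normalization,
paired moderated-t differential calling, DEL-DEM co-expression, DEM term
enrichment and DEL function prediction, cis-pair detection, TF trans
enrichment with core-TF identification, and Cytoscape-ready exports.
An empty differential set at any point propagates empty tables downstream
with a warning rather than an error.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import os
from pathlib import Path

import networkx as nx
import pandas as pd

from . import cis_regulation, coexpression, diffexpr, enrichment, preprocess, trans_regulation
from .containers import (
    AnalysisConfig,
    ExpressionMatrix,
    GeneAnnotationTable,
    GeneSetCollection,
)
from .io_formats import write_network_sif, write_table

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineResult:
    de: diffexpr.DEResults
    chromosome_summary: pd.DataFrame
    coexp_edges: pd.DataFrame
    dem_enrichment: dict[str, pd.DataFrame]  # per direction: 'up', 'down'
    predictions: pd.DataFrame
    term_frequency: pd.DataFrame
    cis: pd.DataFrame
    trans_predictions: pd.DataFrame
    tf_frequency: trans_regulation.TFFrequency
    pair_network: nx.Graph
    triple_network: nx.Graph
    summary: dict


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(
    config: AnalysisConfig,
    expression: ExpressionMatrix,
    annotation: GeneAnnotationTable,
    term_sets: GeneSetCollection,
    tf_sets: GeneSetCollection,
    outdir: str | os.PathLike | None = None,
    skip_flag_filter: bool = False,
) -> PipelineResult:
    """Run every stage on validated inputs; optionally write all outputs."""
    matrix = _stage("preprocess")(preprocess.preprocess)(
        expression, skip_flag_filter=skip_flag_filter or expression.flags is None
    )
    de = _stage("diffexpr")(diffexpr.differential_expression)(matrix, annotation, config)
    chrom = diffexpr.summarize_by_chromosome(de, annotation)
    if not de.dels or not de.dems:
        logger.warning("empty DEL or DEM set: downstream tables will be empty")
    edges = _stage("coexpression")(coexpression.build_coexpression_network)(
        matrix, de.dels, de.dems, config
    )
    # enrichment background: measured coding genes (queries are DEM lists)
    universe = {
        g for g in matrix.gene_ids
        if annotation.table.at[g, "biotype"] == "mRNA"
    }
    dem_enrichment = {
        "up": _stage("enrichment")(enrichment.enrich_gene_set)(
            de.dems_up, term_sets, universe, ease=config.ease,
        ),
        "down": _stage("enrichment")(enrichment.enrich_gene_set)(
            de.dems_down, term_sets, universe, ease=config.ease,
        ),
    }
    predictions, term_freq = _stage("function_prediction")(
        enrichment.predict_lncrna_functions
    )(edges, term_sets, universe, config)
    cis = _stage("cis")(cis_regulation.cis_pairs)(edges, annotation, config)
    if len(edges) and de.dems:
        trans = _stage("trans")(trans_regulation.tf_enrichment)(edges, tf_sets, de.dems)
    else:
        trans = pd.DataFrame(columns=trans_regulation.TRANS_COLUMNS)
    tf_freq = trans_regulation.tf_frequency(trans, config.top_predictions)
    pair_net, triple_net = _stage("networks")(trans_regulation.build_regulatory_network)(
        trans, edges, tf_sets, config
    )
    summary = {
        "seed": config.seed,
        "thresholds": {
            "fc": config.fc_threshold,
            "p": config.p_threshold,
            "pcc": config.pcc_threshold,
            "coexp_p": config.coexp_p_threshold,
            "cis_window": config.cis_window,
            "top_predictions": config.top_predictions,
            "top_tf_pairs": config.top_tf_pairs,
            "top_triples": config.top_triples,
        },
        "counts": {
            "genes_analyzed": len(matrix.gene_ids),
            "dem_up": len(de.dems_up),
            "dem_down": len(de.dems_down),
            "dem_total": len(de.dems),
            "del_up": len(de.dels_up),
            "del_down": len(de.dels_down),
            "del_total": len(de.dels),
            "de_total": len(de.dems) + len(de.dels),
            "coexp_edges": len(edges),
            "function_predictions": len(predictions),
            "cis_pairs": len(cis),
            "trans_predictions": len(trans),
            "core_tf": tf_freq.core_tf,
        },
    }
    result = PipelineResult(
        de, chrom, edges, dem_enrichment, predictions, term_freq, cis,
        trans, tf_freq, pair_net, triple_net, summary,
    )
    if outdir is not None:
        write_results(result, outdir)
    return result


def write_results(result: PipelineResult, outdir: str | os.PathLike) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    records = result.de.records.reset_index(names="gene")
    write_table(records, out / "differential_expression.tsv")
    write_table(result.chromosome_summary, out / "chromosome_summary.tsv")
    write_table(result.coexp_edges, out / "coexpression_edges.tsv")
    for direction, table in result.dem_enrichment.items():
        write_table(table, out / f"dem_enrichment_{direction}.tsv")
    write_table(result.predictions, out / "function_predictions.tsv")
    write_table(result.term_frequency, out / "term_frequency.tsv")
    write_table(result.cis, out / "cis_pairs.tsv")
    write_table(result.trans_predictions, out / "trans_predictions.tsv")
    write_table(result.tf_frequency.table, out / "tf_frequency.tsv")
    write_network_sif(result.pair_network, out / "pair_network.sif",
                      out / "pair_network_nodes.tsv")
    write_network_sif(result.triple_network, out / "triple_network.sif",
                      out / "triple_network_nodes.tsv")
    with open(out / "run_summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
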