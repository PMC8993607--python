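"""TF trans-regulation analysis and core-TF identification.

Tests each TF's target set for over-representation among every DEL's
co-expressed DEMs (hypergeometric, universe = all DEMs), pools and ranks
all (lncRNA, TF) predictions by p, counts TF frequencies over the top 500,
names the most frequent TF the core TF, and exports the top-100 pair and
top-10 triple networks as SIF files Cytoscape can open.
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import analysis_config, load_inputs, parse_args

from lncnet.coexpression import build_coexpression_network
from lncnet.diffexpr import differential_expression
from lncnet.io_formats import write_network_sif, write_table
from lncnet.preprocess import preprocess
from lncnet.trans_regulation import build_regulatory_network, tf_enrichment, tf_frequency


def main():
    args = parse_args(__doc__)
    expression, annotation, _, tf_sets, truth = load_inputs(args.outdir)
    cfg = analysis_config(args.seed)
    matrix = preprocess(expression)
    de = differential_expression(matrix, annotation, cfg)
    edges = build_coexpression_network(matrix, de.dels, de.dems, cfg)
    preds = tf_enrichment(edges, tf_sets, de.dems)
    freq = tf_frequency(preds, cfg.top_predictions)
    write_table(preds, args.outdir / "trans_predictions.tsv")
    write_table(freq.table, args.outdir / "tf_frequency.tsv")
    pair_net, triple_net = build_regulatory_network(preds, edges, tf_sets, cfg)
    write_network_sif(pair_net, args.outdir / "pair_network.sif",
                      args.outdir / "pair_network_nodes.tsv")
    write_network_sif(triple_net, args.outdir / "triple_network.sif",
                      args.outdir / "triple_network_nodes.tsv")
    print(f"{len(preds)} (lncRNA, TF) predictions; TF frequency over the "
          f"top {cfg.top_predictions}:")
    print(freq.table.head(5).to_string(index=False))
    marker = "matches" if freq.core_tf == truth["core_tf"] else "differs from"
    print(f"core TF: {freq.core_tf} ({marker} the planted core TF "
          f"{truth['core_tf']}){' [tie]' if freq.tie else ''}")
    print(f"pair network: {pair_net.number_of_nodes()} nodes / "
          f"{pair_net.number_of_edges()} edges; triple network: "
          f"{triple_net.number_of_nodes()} nodes / {triple_net.number_of_edges()} edges")


if __name__ == "__main__":
    main()
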