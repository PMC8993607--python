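"""Build the DEL-DEM Pearson co-expression network.

Correlates every differential lncRNA with every differential mRNA across
all six arrays and keeps pairs with |r| > 0.7 and correlation p < 0.05
(at n = 6 the p criterion, |r| > ~0.811, is the stricter one), then
writes the edge table that function prediction, cis and trans analysis
consume.
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import analysis_config, load_inputs, parse_args

from lncnet.coexpression import build_coexpression_network, min_significant_r
from lncnet.diffexpr import differential_expression
from lncnet.io_formats import write_table
from lncnet.preprocess import preprocess


def main():
    args = parse_args(__doc__)
    expression, annotation, *_, truth = load_inputs(args.outdir)
    cfg = analysis_config(args.seed)
    matrix = preprocess(expression)
    de = differential_expression(matrix, annotation, cfg)
    edges = build_coexpression_network(matrix, de.dels, de.dems, cfg)
    write_table(edges, args.outdir / "coexpression_edges.tsv")
    n = len(matrix.sample_ids)
    print(f"effective |r| cutoff at n={n}, alpha=0.05: {min_significant_r(n):.4f}")
    print(f"{len(edges)} edges among {len(de.dels)} DELs x {len(de.dems)} DEMs "
          f"(density {len(edges) / max(len(de.dels) * len(de.dems), 1):.2f})")
    mod = truth["modules"][0]
    mod_l, mod_m = set(mod["lncrna"]), set(mod["mrna"])
    in_module = sum((l in mod_l) and (m in mod_m)
                    for l, m in zip(edges["lncrna"], edges["mrna"]))
    print(f"planted-module edges retained: {in_module} of {len(mod_l) * len(mod_m)} "
          "possible module pairs")


if __name__ == "__main__":
    main()
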