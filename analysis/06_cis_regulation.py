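"""Detect cis-regulated lncRNA-gene pairs.

Intersects the co-expression network with the genomic window rule: a DEL
and a coding gene on the same chromosome with an interval gap of at most
100 kb. Writes one row per pair with Pearson r, Pearson p and the cis
distance, and compares against the planted pairs.
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import analysis_config, load_inputs, parse_args

from lncnet.cis_regulation import cis_pairs
from lncnet.coexpression import build_coexpression_network
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
    cis = cis_pairs(edges, annotation, cfg)
    write_table(cis, args.outdir / "cis_pairs.tsv")
    print(f"{len(cis)} cis pairs among {cis['lncrna'].nunique()} DELs "
          f"(window {cfg.cis_window} bp)")
    planted = {(l, m) for l, m, _ in map(tuple, truth["cis_pairs"])}
    found = set(zip(cis["lncrna"], cis["gene"]))
    print(f"planted cis pairs recovered: {len(found & planted)}/{len(planted)}; "
          f"spurious: {len(found - planted)}")


if __name__ == "__main__":
    main()
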