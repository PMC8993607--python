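"""Call differential mRNAs (DEMs) and lncRNAs (DELs).

Applies the paired empirical-Bayes moderated t-test to tumor-minus-normal
log2 ratios and the dual threshold (linear fold change >= 2, p < 0.05),
then writes the per-gene table, the per-class count summary, and the
per-chromosome distribution of differential genes.
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import analysis_config, load_inputs, parse_args

from lncnet.diffexpr import count_summary, differential_expression, summarize_by_chromosome
from lncnet.io_formats import write_table
from lncnet.preprocess import preprocess


def main():
    args = parse_args(__doc__)
    expression, annotation, *_ , truth = load_inputs(args.outdir)
    matrix = preprocess(expression)
    de = differential_expression(matrix, annotation, analysis_config(args.seed))
    write_table(de.records.reset_index(names="gene"),
                args.outdir / "differential_expression.tsv")
    counts = count_summary(len(de.dems_up), len(de.dems_down),
                           len(de.dels_up), len(de.dels_down))
    write_table(counts, args.outdir / "de_counts.tsv")
    write_table(summarize_by_chromosome(de, annotation),
                args.outdir / "chromosome_summary.tsv")
    print(counts.to_string(index=False))
    planted = set(truth["de"])
    called = set(de.dems) | set(de.dels)
    recall = len(called & planted) / len(planted)
    print(f"planted DE genes recovered: {len(called & planted)}/{len(planted)} "
          f"({recall:.0%}); false calls: {len(called - planted)}")


if __name__ == "__main__":
    main()
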