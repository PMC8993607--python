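"""Detection filtering and quantile normalization.

Drops probes that are not 100% present ('P') in at least one sample group
and quantile-normalizes the remaining intensities so every array shares
one distribution, then writes the normalized matrix consumed by the
differential-expression stage.
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import data_dir, load_inputs, parse_args

from lncnet import write_expression_table
from lncnet.preprocess import filter_present, preprocess


def main():
    args = parse_args(__doc__)
    expression, *_ = load_inputs(args.outdir)
    kept = filter_present(expression)
    normalized = preprocess(expression)
    d = data_dir(args.outdir)
    write_expression_table(normalized, d / "normalized.tsv", d / "samples.tsv")
    print(f"presence filter kept {len(kept)}/{len(expression.gene_ids)} probes")
    print(f"wrote quantile-normalized matrix to {d / 'normalized.tsv'}")


if __name__ == "__main__":
    main()
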