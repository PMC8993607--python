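"""Simulate the paired tumor/normal expression study.

Generates the default synthetic dataset — 3 tissue pairs, 200 mRNA and 60
lncRNA probes, one dysregulated co-expression module with a planted core
TF, planted cis pairs and term annotations — and writes every input the
downstream stages read, plus the planted ground truth for later
comparison.
"""
import dataclasses
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import data_dir, parse_args

from lncnet import generate_dataset, write_expression_table, write_gene_annotation, write_gmt
from lncnet.containers import GeneSetCollection


def main():
    args = parse_args(__doc__)
    ds = generate_dataset(seed=args.seed)
    d = data_dir(args.outdir)
    d.mkdir(parents=True, exist_ok=True)
    write_expression_table(ds.expression, d / "expression.tsv", d / "samples.tsv",
                           d / "flags.tsv")
    write_gene_annotation(ds.annotation, d / "annotation.bed")
    write_gmt(ds.tf_sets, d / "tf_sets.gmt")
    for category in ds.term_sets.categories:
        write_gmt(GeneSetCollection(ds.term_sets.by_category(category)),
                  d / f"term_sets_{category}.gmt")
    truth = ds.truth
    (d / "truth.json").write_text(json.dumps({
        "de": truth.de,
        "modules": truth.modules,
        "cis_pairs": truth.cis_pairs,
        "core_tf": truth.core_tf,
        "term_members": {t: sorted(m) for t, m in truth.term_members.items()},
        "config": dataclasses.asdict(ds.config),
    }, indent=2) + "\n")
    print(f"wrote simulated study (seed {args.seed}) to {d}")
    print(f"  genes: {len(ds.expression.gene_ids)} "
          f"({ds.config.n_mrna} mRNA + {ds.config.n_lncrna} lncRNA), "
          f"samples: {len(ds.expression.sample_ids)}")
    print(f"  planted: {len(truth.de)} DE genes, "
          f"module of {ds.config.module_size_mrna}+{ds.config.module_size_lncrna} genes, "
          f"{len(truth.cis_pairs)} cis pairs, core TF {truth.core_tf}")


if __name__ == "__main__":
    main()
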