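"""Shared argument handling for the analysis drivers."""
import argparse
import json
from pathlib import Path

from lncnet import (
    AnalysisConfig,
    read_expression_table,
    read_gene_annotation,
    read_gmt,
)


def parse_args(description: str):
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    parser.add_argument("--seed", type=int, default=1)
    return parser.parse_args()


def data_dir(outdir: Path) -> Path:
    return outdir / "data"


def load_inputs(outdir: Path):
    """Load the simulated study written by 01_simulate.py."""
    from lncnet import GeneSetCollection

    d = data_dir(outdir)
    expression = read_expression_table(
        d / "expression.tsv", d / "samples.tsv", d / "flags.tsv"
    )
    annotation = read_gene_annotation(d / "annotation.bed")
    term_sets = GeneSetCollection(
        s
        for path in sorted(d.glob("term_sets_*.gmt"))
        for s in read_gmt(path, category=path.stem.removeprefix("term_sets_"))
    )
    tf_sets = read_gmt(d / "tf_sets.gmt", category="TF")
    truth = json.loads((d / "truth.json").read_text())
    return expression, annotation, term_sets, tf_sets, truth


def analysis_config(seed: int) -> AnalysisConfig:
    return AnalysisConfig(seed=seed)
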