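import numpy as np
import pandas as pd
import pytest

from lncnet import AnalysisConfig, ExpressionMatrix, generate_dataset, run_pipeline


def make_matrix(values, flags=None, n_pairs=None):
    """Build a small paired ExpressionMatrix from a 2-D array.

    Columns alternate tumor/normal per pair: P1T, P1N, P2T, P2N, ...
    """
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    assert n_samples % 2 == 0
    n_pairs = n_samples // 2
    sample_ids, pair_ids, conditions = [], [], []
    for i in range(1, n_pairs + 1):
        for cond, tag in (("tumor", "T"), ("normal", "N")):
            sample_ids.append(f"P{i}{tag}")
            pair_ids.append(f"P{i}")
            conditions.append(cond)
    genes = [f"G{i}" for i in range(1, n_genes + 1)]
    vdf = pd.DataFrame(values, index=genes, columns=sample_ids)
    meta = pd.DataFrame({"pair_id": pair_ids, "condition": conditions}, index=sample_ids)
    fdf = None
    if flags is not None:
        fdf = pd.DataFrame(np.asarray(flags, dtype=str), index=genes, columns=sample_ids)
    return ExpressionMatrix(vdf, meta, fdf)


@pytest.fixture(scope="session")
def dataset():
    return generate_dataset(seed=1)


@pytest.fixture(scope="session")
def pipeline_result(dataset):
    return run_pipeline(
        AnalysisConfig(seed=1),
        dataset.expression,
        dataset.annotation,
        dataset.term_sets,
        dataset.tf_sets,
    )
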