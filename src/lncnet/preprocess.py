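"""Probe presence filtering and quantile normalization.

Mirrors the array-preprocessing contract of single-channel Agilent data:
a probe is retained when at least one sample group is 100% 'P' (present),
and intensities are quantile-normalized so every array shares one
empirical distribution.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import NORMAL, TUMOR, ExpressionMatrix, ValidationError


def filter_present(matrix: ExpressionMatrix) -> list[str]:
    """Gene ids passing the detection filter, input order preserved.

    A gene is kept iff *all* tumor flags are 'P' or *all* normal flags are
    'P'. 'M' (marginal) counts as not detected. Requires detection flags.
    """
    if matrix.flags is None:
        raise ValidationError(
            "matrix has no detection flags; skip the presence-filter stage"
        )
    flags = matrix.flags
    tumor = flags[matrix.samples_for(TUMOR)].to_numpy() == "P"
    normal = flags[matrix.samples_for(NORMAL)].to_numpy() == "P"
    keep = tumor.all(axis=1) | normal.all(axis=1)
    return [g for g, k in zip(matrix.gene_ids, keep) if k]


def quantile_normalize_frame(values: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns of a genes x samples frame.

    Every column is mapped onto the reference distribution formed by the
    per-rank cross-column means. Within-column rank order is preserved;
    tied values receive the mean of their tied rank slots' reference
    values, so equal inputs map to equal outputs.
    """
    arr = values.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValidationError("non-finite values cannot be quantile-normalized")
    if arr.size == 0:
        raise ValidationError("empty matrix")
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        mapped = np.empty_like(reference)
        mapped[order] = reference
        # ties: average the reference values over each tied slot group
        uniq, inverse = np.unique(col, return_inverse=True)
        if len(uniq) < len(col):
            sums = np.bincount(inverse, weights=mapped)
            counts = np.bincount(inverse)
            mapped = (sums / counts)[inverse]
        out[:, j] = mapped
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize an expression matrix (metadata and flags kept)."""
    return ExpressionMatrix(
        quantile_normalize_frame(matrix.values),
        matrix.sample_meta.copy(),
        None if matrix.flags is None else matrix.flags.copy(),
    )


def preprocess(matrix: ExpressionMatrix, skip_flag_filter: bool = False) -> ExpressionMatrix:
    """Presence filter (when flags exist) followed by quantile normalization."""
    if matrix.flags is not None and not skip_flag_filter:
        matrix = matrix.subset_genes(filter_present(matrix))
    return quantile_normalize(matrix)
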