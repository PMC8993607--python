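"""Cis-regulation: genomic proximity intersected with co-expression.

A lncRNA is called a potential cis-regulator of a coding gene when the two
are (a) on the same chromosome with an interval gap of at most the cis
window (100 kb by default, inclusive, symmetric — strand is ignored) and
(b) significantly co-expressed. Distances are measured between gene-body
intervals (0-based half-open); overlapping or abutting intervals have
distance zero.
"""
from __future__ import annotations

import pandas as pd

from .containers import (
    BIOTYPE_MRNA,
    AnalysisConfig,
    GeneAnnotationTable,
    ValidationError,
)

CIS_COLUMNS = ["lncrna", "gene", "pearson_r", "pearson_p", "cis_distance"]


def genomic_distance(
    interval_a: tuple[str, int, int], interval_b: tuple[str, int, int]
) -> int | None:
    """Gap in bp between two half-open intervals; ``None`` if on different
    chromosomes; 0 when the intervals overlap or abut."""
    chrom_a, start_a, end_a = interval_a
    chrom_b, start_b, end_b = interval_b
    if chrom_a != chrom_b:
        return None
    return max(start_a - end_b, start_b - end_a, 0)


def find_cis_candidates(
    lncrna: str, annotation: GeneAnnotationTable, window: int
) -> list[str]:
    """Coding genes within ``window`` bp of the lncRNA (inclusive), sorted."""
    if lncrna not in annotation:
        raise ValidationError(f"lncRNA {lncrna!r} not annotated")
    iv = annotation.interval(lncrna)
    out = []
    for gene in annotation.ids_of_biotype(BIOTYPE_MRNA):
        d = genomic_distance(iv, annotation.interval(gene))
        if d is not None and d <= window:
            out.append(gene)
    return sorted(out)


def cis_pairs(
    coexp_edges: pd.DataFrame,
    annotation: GeneAnnotationTable,
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Co-expression edges whose endpoints also satisfy the window rule.

    One row per retained pair with the correlation, its p-value and the
    genomic gap; sorted by (lncrna, gene). A subset of the input edges by
    construction.
    """
    rows = []
    for edge in coexp_edges.itertuples(index=False):
        d = genomic_distance(
            annotation.interval(edge.lncrna), annotation.interval(edge.mrna)
        )
        if d is not None and d <= config.cis_window:
            rows.append((edge.lncrna, edge.mrna, edge.r, edge.p, d))
    out = pd.DataFrame(rows, columns=CIS_COLUMNS)
    return out.sort_values(["lncrna", "gene"], kind="mergesort").reset_index(drop=True)
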