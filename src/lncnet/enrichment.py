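"""Hypergeometric gene-set enrichment and guilt-by-association prediction.

Enrichment of a query gene list against a named collection uses the
hypergeometric upper tail P[X >= k] with Benjamini-Hochberg FDR per
category. A lncRNA's functions are predicted from the enriched terms of
its co-expressed coding genes; predictions from all lncRNAs are pooled,
ranked by ascending p, truncated to a fixed top list, and term frequencies
within that list are counted.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AnalysisConfig, GeneSetCollection, ValidationError
from .coexpression import coexpressed_partners

ENRICH_COLUMNS = [
    "set_id", "category", "description", "k", "n", "K", "N",
    "p", "fold_enrichment", "fdr",
]


def hypergeom_sf(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P[X >= k].

    X counts members of a K-sized set among n draws (without replacement)
    from a universe of N. Parameters are validated; the result lies in
    (0, 1] (underflow is clamped to the smallest positive float).
    """
    if not (0 <= K <= N):
        raise ValidationError(f"need 0 <= K <= N, got K={K}, N={N}")
    if not (0 <= n <= N):
        raise ValidationError(f"need 0 <= n <= N, got n={n}, N={N}")
    if not (0 <= k <= min(n, K)):
        raise ValidationError(f"need 0 <= k <= min(n, K), got k={k}")
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return float(np.clip(p, np.finfo(float).tiny, 1.0))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    return stats.false_discovery_control(p, method="bh")


def enrich_gene_set(
    query_genes,
    collection: GeneSetCollection,
    universe,
    ease: bool = False,
    restrict_to_annotated: bool = False,
) -> pd.DataFrame:
    """Hypergeometric enrichment of a query list against a collection.

    Sets are intersected with the universe before testing and BH
    correction runs across each category's tested sets. Only sets
    overlapping the query (k >= 1) are reported. With
    ``restrict_to_annotated=True`` the universe is additionally narrowed,
    per category, to genes annotated in that category (the DAVID-like
    measured-and-annotated background the pipeline uses). With
    ``ease=True`` the DAVID-style EASE variant tests k-1 instead of k.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    query = set(query_genes)
    outside = sorted(query - universe)
    if outside:
        raise ValidationError(f"query genes outside the universe: {outside[:5]}")
    rows = []
    for category in collection.categories:
        cat_sets = collection.by_category(category)
        cat_universe = universe
        if restrict_to_annotated:
            annotated: set[str] = set()
            for s in cat_sets:
                annotated |= s.members
            cat_universe = universe & annotated
        if not cat_universe:
            continue
        cat_query = query & cat_universe
        n = len(cat_query)
        N = len(cat_universe)
        cat_rows = []
        for s in sorted(cat_sets, key=lambda s: s.set_id):
            members = s.members & cat_universe
            K = len(members)
            k = len(cat_query & members)
            if k < 1:
                continue
            p = hypergeom_sf(max(k - 1, 0) if ease else k, K, n, N)
            fe = (k / n) / (K / N)
            cat_rows.append((s.set_id, category, s.description, k, n, K, N, p, fe))
        if not cat_rows:
            continue
        cat_df = pd.DataFrame(
            cat_rows, columns=ENRICH_COLUMNS[:-1]
        )
        cat_df["fdr"] = bh_fdr(cat_df["p"].to_numpy())
        rows.append(cat_df)
    if not rows:
        return pd.DataFrame(columns=ENRICH_COLUMNS)
    return pd.concat(rows, ignore_index=True)


def predict_lncrna_functions(
    coexp_edges: pd.DataFrame,
    collection: GeneSetCollection,
    universe,
    config: AnalysisConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Guilt-by-association function prediction for every lncRNA.

    For each lncRNA in the co-expression network, its co-expressed coding
    genes are tested for term enrichment; all (lncRNA, term) rows are
    pooled, sorted by ascending p (ties broken by lncrna then set_id),
    ranked, and truncated to ``config.top_predictions``. The second return
    value counts, per (category, term), how often the term appears in the
    retained list (``count``) and the summed query/set overlap of those
    rows (``total_overlap``).
    """
    universe = set(universe)
    pooled = []
    for lnc, partners in sorted(coexpressed_partners(coexp_edges).items()):
        res = enrich_gene_set(partners & universe, collection, universe,
                              ease=config.ease)
        for row in res.itertuples(index=False):
            pooled.append((lnc, row.set_id, row.category, row.p, row.k))
    predictions = pd.DataFrame(
        pooled, columns=["lncrna", "set_id", "category", "p", "k"]
    )
    predictions = predictions.sort_values(
        ["p", "lncrna", "set_id"], kind="mergesort"
    ).reset_index(drop=True)
    predictions["rank"] = np.arange(1, len(predictions) + 1)
    top = predictions.head(config.top_predictions)
    freq = (
        top.groupby(["category", "set_id"], observed=True)
        .agg(count=("set_id", "size"), total_overlap=("k", "sum"))
        .reset_index()
        .sort_values(["category", "count", "set_id"],
                     ascending=[True, False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    return top.reset_index(drop=True), freq
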