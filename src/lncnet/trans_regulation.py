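"""TF trans-regulation inference and regulatory-network construction.

For every lncRNA in the co-expression network, each transcription factor's
target set is tested for over-representation among the lncRNA's
co-expressed differential mRNAs (hypergeometric upper tail; the universe
is the full set of differential mRNAs — the population the co-expressed
sets are drawn from). All (lncRNA, TF) rows are ranked globally by
ascending p; TF frequencies are counted over the top of that ranking and
the most frequent TF is reported as the core TF. The top pairs and top
triples are assembled into Cytoscape-ready networks.
"""
from __future__ import annotations

import dataclasses

import networkx as nx
import numpy as np
import pandas as pd

from .containers import AnalysisConfig, GeneSetCollection, ValidationError
from .coexpression import coexpressed_partners
from .enrichment import hypergeom_sf

TRANS_COLUMNS = ["lncrna", "tf", "k", "K", "n", "N", "p", "rank"]


def tf_enrichment(
    coexp_edges: pd.DataFrame,
    tf_collection: GeneSetCollection,
    universe,
) -> pd.DataFrame:
    """Per-(lncRNA, TF) hypergeometric enrichment, globally ranked by p.

    ``universe`` is the list of all differential mRNAs. TF target sets are
    intersected with the universe; only rows with overlap k >= 1 are
    emitted. Ties in p are broken by (lncrna, tf) so ranks are stable.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe for TF enrichment")
    N = len(universe)
    targets = {
        s.set_id: s.members & universe
        for s in sorted(tf_collection, key=lambda s: s.set_id)
    }
    rows = []
    for lnc, partners in sorted(coexpressed_partners(coexp_edges).items()):
        query = partners & universe
        n = len(query)
        if n == 0:
            continue
        for tf, members in targets.items():
            K = len(members)
            k = len(query & members)
            if k < 1:
                continue
            rows.append((lnc, tf, k, K, n, N, hypergeom_sf(k, K, n, N)))
    out = pd.DataFrame(rows, columns=TRANS_COLUMNS[:-1])
    out = out.sort_values(["p", "lncrna", "tf"], kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


@dataclasses.dataclass
class TFFrequency:
    table: pd.DataFrame  # columns: tf, count, is_core
    core_tf: str | None
    tie: bool  # True when several TFs share the maximal count


def tf_frequency(predictions: pd.DataFrame, top_n: int) -> TFFrequency:
    """Count each TF's appearances among the ``top_n`` best predictions.

    The core TF is the argmax count; ties are broken lexicographically and
    flagged. Empty predictions give an empty table and no core TF.
    """
    if len(predictions) == 0:
        return TFFrequency(pd.DataFrame(columns=["tf", "count", "is_core"]), None, False)
    top = predictions.nsmallest(min(top_n, len(predictions)), "rank")
    counts = (
        top.groupby("tf").size().rename("count").reset_index()
        .sort_values(["count", "tf"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    core = str(counts.at[0, "tf"])
    tie = bool((counts["count"] == counts.at[0, "count"]).sum() > 1)
    counts["is_core"] = counts["tf"] == core
    return TFFrequency(counts, core, tie)


def _add_typed_edge(g: nx.Graph, u: str, ut: str, v: str, vt: str, relation: str) -> None:
    if u == v:
        return  # no self-loops
    g.add_node(u, node_type=ut)
    g.add_node(v, node_type=vt)
    g.add_edge(u, v, relation=relation)


def build_regulatory_network(
    predictions: pd.DataFrame,
    coexp_edges: pd.DataFrame,
    tf_collection: GeneSetCollection,
    config: AnalysisConfig,
) -> tuple[nx.Graph, nx.Graph]:
    """Build the top-pairs and top-triples regulatory networks.

    The pair network contains the best ``top_tf_pairs`` (lncRNA, TF) rows
    as ``trans`` edges. The triple network expands each of the best
    ``top_triples`` rows into its overlap mRNAs m, with edges
    lncRNA-TF (trans), TF-m (target), and lncRNA-m (coexp).
    """
    partners = coexpressed_partners(coexp_edges)
    pair_net = nx.Graph()
    if len(predictions) == 0:
        return pair_net, nx.Graph()
    for row in predictions.nsmallest(
        min(config.top_tf_pairs, len(predictions)), "rank"
    ).itertuples(index=False):
        _add_typed_edge(pair_net, row.lncrna, "lncRNA", row.tf, "TF", "trans")
    triple_net = nx.Graph()
    for row in predictions.nsmallest(
        min(config.top_triples, len(predictions)), "rank"
    ).itertuples(index=False):
        _add_typed_edge(triple_net, row.lncrna, "lncRNA", row.tf, "TF", "trans")
        overlap = sorted(partners.get(row.lncrna, set()) & tf_collection[row.tf].members)
        for m in overlap:
            _add_typed_edge(triple_net, row.tf, "TF", m, "gene", "target")
            _add_typed_edge(triple_net, row.lncrna, "lncRNA", m, "gene", "coexp")
    return pair_net, triple_net
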