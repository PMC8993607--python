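import itertools

import numpy as np
import pandas as pd
import pytest

from lncnet import AnalysisConfig, ValidationError
from lncnet.containers import GeneSet, GeneSetCollection
from lncnet.trans_regulation import build_regulatory_network, tf_enrichment, tf_frequency


def tf_collection(sets):
    return GeneSetCollection(
        [GeneSet(name, "tf", frozenset(members), "TF") for name, members in sets.items()]
    )


def edges_frame(pairs):
    return pd.DataFrame(
        [(l, m, 0.9, 0.01, 6) for l, m in pairs],
        columns=["lncrna", "mrna", "r", "p", "n"],
    )


def enumeration_sf(k, K, n, N):
    marked = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


class TestTFEnrichment:
    universe = [f"g{i}" for i in range(1, 11)]

    def test_maximal_overlap_attains_min_p(self):
        coll = tf_collection({"TF_A": {"g1", "g2", "g3"}, "TF_B": {"g1", "g5", "g9"}})
        edges = edges_frame([("L1", "g1"), ("L1", "g2"), ("L1", "g3")])
        res = tf_enrichment(edges, coll, self.universe)
        res = res.set_index("tf")
        assert res.loc["TF_A", "p"] == res["p"].min()
        assert res.loc["TF_A", ["k", "n", "K"]].tolist() == [3, 3, 3]

    def test_zero_overlap_no_row(self):
        coll = tf_collection({"TF_A": {"g9"}})
        edges = edges_frame([("L1", "g1")])
        res = tf_enrichment(edges, coll, self.universe)
        assert len(res) == 0

    def test_shared_hypergeometric_example(self):
        # k=3 of the lncRNA's 5 partners fall in a 4-gene target set, N=10
        coll = tf_collection({"TF_A": {"g1", "g2", "g3", "g4"}})
        edges = edges_frame([("L1", g) for g in ("g1", "g2", "g3", "g5", "g6")])
        res = tf_enrichment(edges, coll, self.universe)
        assert res.iloc[0]["p"] == pytest.approx(66 / 252, abs=1e-12)

    def test_matches_enumeration_on_small_instance(self):
        rng = np.random.default_rng(0)
        genes = self.universe
        coll = tf_collection(
            {f"TF{j}": set(rng.choice(genes, size=4, replace=False)) for j in range(3)}
        )
        pairs = [(f"L{i}", g) for i in range(3) for g in genes if rng.random() < 0.5]
        res = tf_enrichment(edges_frame(pairs), coll, genes)
        partners = {}
        for l, g in pairs:
            partners.setdefault(l, set()).add(g)
        index = {g: i for i, g in enumerate(genes)}
        for row in res.itertuples(index=False):
            members = coll[row.tf].members
            # remap to integer labels for the enumeration oracle
            K = len(members)
            n = len(partners[row.lncrna])
            k = len(partners[row.lncrna] & members)
            relabeled = enumeration_sf(k, K, n, len(genes))
            assert row.p == pytest.approx(relabeled, abs=1e-12)

    def test_rank_is_stable_sorted_by_p(self):
        coll = tf_collection({"TF_A": {"g1"}, "TF_B": {"g1"}})
        edges = edges_frame([("L1", "g1"), ("L2", "g1")])
        res = tf_enrichment(edges, coll, self.universe)
        assert res["rank"].tolist() == [1, 2, 3, 4]
        assert res[["p", "lncrna", "tf"]].values.tolist() == sorted(
            res[["p", "lncrna", "tf"]].values.tolist()
        )

    def test_empty_universe_rejected(self):
        with pytest.raises(ValidationError):
            tf_enrichment(edges_frame([("L1", "g1")]), tf_collection({"A": {"g1"}}), [])


class TestTFFrequency:
    def test_unanimous(self):
        preds = pd.DataFrame(
            {"lncrna": ["L1", "L2", "L3"], "tf": ["TF_A"] * 3,
             "p": [0.01, 0.02, 0.03], "rank": [1, 2, 3]}
        )
        freq = tf_frequency(preds, top_n=500)
        assert freq.core_tf == "TF_A" and not freq.tie
        assert freq.table.iloc[0]["count"] == 3

    def test_top_n_larger_than_rows(self):
        preds = pd.DataFrame(
            {"lncrna": ["L1", "L2"], "tf": ["A", "B"], "p": [0.1, 0.2], "rank": [1, 2]}
        )
        freq = tf_frequency(preds, top_n=10)
        assert freq.table["count"].sum() == 2

    def test_counts_sum_to_top_n(self):
        rng = np.random.default_rng(1)
        preds = pd.DataFrame(
            {
                "lncrna": [f"L{i}" for i in range(40)],
                "tf": rng.choice(["A", "B", "C"], size=40),
                "p": np.sort(rng.uniform(size=40)),
                "rank": np.arange(1, 41),
            }
        )
        freq = tf_frequency(preds, top_n=25)
        assert freq.table["count"].sum() == 25

    def test_empty_predictions(self):
        freq = tf_frequency(pd.DataFrame(columns=["lncrna", "tf", "p", "rank"]), 500)
        assert freq.core_tf is None and len(freq.table) == 0

    def test_tie_flagged_and_broken_lexicographically(self):
        preds = pd.DataFrame(
            {"lncrna": ["L1", "L2"], "tf": ["B", "A"], "p": [0.1, 0.2], "rank": [1, 2]}
        )
        freq = tf_frequency(preds, top_n=10)
        assert freq.tie and freq.core_tf == "A"


class TestRegulatoryNetwork:
    def test_single_triple_construction(self):
        coll = tf_collection({"TF_A": {"g1", "g2"}})
        edges = edges_frame([("L1", "g1"), ("L1", "g2")])
        preds = tf_enrichment(edges, coll, ["g1", "g2", "g3"])
        pair_net, triple_net = build_regulatory_network(
            preds, edges, coll, AnalysisConfig()
        )
        assert set(pair_net.nodes) == {"L1", "TF_A"}
        assert triple_net.number_of_nodes() == 4
        expected = {
            frozenset(e): rel
            for e, rel in [
                (("L1", "TF_A"), "trans"), (("TF_A", "g1"), "target"),
                (("TF_A", "g2"), "target"), (("L1", "g1"), "coexp"),
                (("L1", "g2"), "coexp"),
            ]
        }
        got = {
            frozenset((u, v)): d["relation"] for u, v, d in triple_net.edges(data=True)
        }
        assert got == expected
        types = {n: triple_net.nodes[n]["node_type"] for n in triple_net}
        assert types == {"L1": "lncRNA", "TF_A": "TF", "g1": "gene", "g2": "gene"}

    def test_fewer_predictions_than_cutoff_all_included(self):
        coll = tf_collection({"TF_A": {"g1"}, "TF_B": {"g2"}})
        edges = edges_frame([("L1", "g1"), ("L2", "g2")])
        preds = tf_enrichment(edges, coll, ["g1", "g2"])
        pair_net, _ = build_regulatory_network(preds, edges, coll, AnalysisConfig())
        assert pair_net.number_of_edges() == len(preds)

    def test_deterministic(self, dataset, pipeline_result):
        from lncnet.trans_regulation import tf_enrichment as enr

        res2 = enr(
            pipeline_result.coexp_edges, dataset.tf_sets, pipeline_result.de.dems
        )
        assert res2.equals(pipeline_result.trans_predictions)
        n1, t1 = build_regulatory_network(
            res2, pipeline_result.coexp_edges, dataset.tf_sets, AnalysisConfig()
        )
        assert n1.number_of_nodes() == pipeline_result.pair_network.number_of_nodes()
        assert t1.number_of_edges() == pipeline_result.triple_network.number_of_edges()


class TestCoreTFRecovery:
    def test_frequency_table_consistency(self, pipeline_result):
        freq = pipeline_result.tf_frequency
        preds = pipeline_result.trans_predictions
        top = preds.nsmallest(min(500, len(preds)), "rank")
        assert freq.table["count"].sum() == len(top)
        assert set(freq.table["tf"]) <= set(top["tf"])

    def test_planted_core_tf_identified(self, dataset, pipeline_result):
        assert pipeline_result.tf_frequency.core_tf == dataset.truth.core_tf
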