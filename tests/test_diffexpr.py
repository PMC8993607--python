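import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special, stats

from lncnet import AnalysisConfig, ValidationError
from lncnet.containers import GeneAnnotationTable
from lncnet.diffexpr import (
    call_differential,
    count_summary,
    moderated_t,
    paired_log_ratios,
    summarize_by_chromosome,
    trigamma_inverse,
)

from conftest import make_matrix


def toy_annotation(genes, biotypes, chroms=None):
    chroms = chroms or ["chr1"] * len(genes)
    df = pd.DataFrame(
        {
            "chrom": chroms,
            "start": range(0, 1000 * len(genes), 1000),
            "end": range(500, 1000 * len(genes) + 500, 1000),
            "biotype": biotypes,
            "strand": ["+"] * len(genes),
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return GeneAnnotationTable(df)


class TestPairedRatios:
    def test_subtraction(self):
        mat = make_matrix([[5.0, 3.0]])
        assert paired_log_ratios(mat).to_numpy() == pytest.approx(np.array([[2.0]]))

    def test_identical_columns_give_zero(self):
        col = np.array([1.0, 2.0, 3.0])
        mat = make_matrix(np.column_stack([col, col, col, col]))
        assert np.all(paired_log_ratios(mat).to_numpy() == 0)

    def test_three_pairs_three_columns(self):
        mat = make_matrix(np.random.default_rng(0).normal(size=(4, 6)))
        assert paired_log_ratios(mat).shape == (4, 3)


def oracle_moderated_t(ratios: np.ndarray):
    """Independent step-by-step transcription of the moderated-t formulas.

    Hyperparameters by moment matching on log s_g^2 with the trigamma
    equation solved by bracketed root finding (not the Newton scheme used
    by the implementation).
    """
    n = ratios.shape[1]
    dg = n - 1
    mean = ratios.mean(axis=1)
    s2 = ratios.var(axis=1, ddof=1)
    z = np.log(s2)
    e = z - special.digamma(dg / 2.0) + math.log(dg / 2.0)
    emean = e.mean()
    evar = np.sum((e - emean) ** 2) / (len(e) - 1)
    target = evar - special.polygamma(1, dg / 2.0)
    if target <= 0:
        d0 = math.inf
        s0_sq = math.exp(emean)
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.full_like(s2, math.inf)
    else:
        half_d0 = optimize.brentq(
            lambda x: special.polygamma(1, x) - target, 1e-6, 1e8, xtol=1e-14
        )
        d0 = 2 * half_d0
        s0_sq = math.exp(emean + special.digamma(half_d0) - math.log(half_d0))
        s2_post = (d0 * s0_sq + dg * s2) / (d0 + dg)
        df_total = np.full_like(s2, d0 + dg)
    t = mean / np.sqrt(s2_post / n)
    p = 2 * stats.t.sf(np.abs(t), df_total)
    return t, p, d0


class TestModeratedT:
    def test_matches_independent_transcription(self):
        rng = np.random.default_rng(7)
        # heterogeneous variances so shrinkage is non-trivial
        sds = rng.uniform(0.1, 1.5, size=50)
        ratios = rng.normal(0, 1, size=(50, 3)) * sds[:, None]
        frame = moderated_t(pd.DataFrame(ratios))
        t_ref, p_ref, d0_ref = oracle_moderated_t(ratios)
        assert math.isfinite(d0_ref)
        assert frame.attrs["d0"] == pytest.approx(d0_ref, abs=1e-6)
        assert frame["t"].to_numpy() == pytest.approx(t_ref, abs=1e-8)
        assert frame["p"].to_numpy() == pytest.approx(p_ref, abs=1e-8)

    def test_all_zero_gene_is_null(self):
        ratios = pd.DataFrame(
            np.vstack([np.zeros(3), np.random.default_rng(1).normal(size=(9, 3))])
        )
        frame = moderated_t(ratios)
        assert frame.iloc[0]["log2fc"] == 0
        assert frame.iloc[0]["t"] == 0
        assert frame.iloc[0]["p"] == 1

    def test_d0_zero_equals_ordinary_t(self):
        rng = np.random.default_rng(2)
        ratios = rng.normal(size=(20, 4))
        frame = moderated_t(pd.DataFrame(ratios), d0=0)
        t_ref, p_ref = stats.ttest_1samp(ratios, 0.0, axis=1).statistic, None
        assert frame["t"].to_numpy() == pytest.approx(t_ref)
        p_ord = 2 * stats.t.sf(np.abs(t_ref), 3)
        assert frame["p"].to_numpy() == pytest.approx(p_ord)

    def test_monotone_in_mean_at_fixed_variance(self):
        base = np.array([[-1.0, 0.0, 1.0]])
        rows = np.vstack([base + m for m in (0.0, 0.5, 1.0, 2.0)])
        rng = np.random.default_rng(3)
        filler = rng.normal(size=(30, 3))
        frame = moderated_t(pd.DataFrame(np.vstack([rows, filler])))
        t_vals = frame["t"].to_numpy()[:4]
        assert np.all(np.diff(t_vals) > 0)

    def test_single_pair_rejected(self):
        with pytest.raises(ValidationError):
            moderated_t(pd.DataFrame(np.ones((5, 1))))


class TestTrigammaInverse:
    @pytest.mark.parametrize("y", [1e-5, 0.01, 0.5, 2.0, 100.0, 1e6])
    def test_round_trip(self, y):
        x = trigamma_inverse(y)
        assert special.polygamma(1, x) == pytest.approx(y, rel=1e-6)


class TestCalling:
    def _records(self, log2fc, p):
        return pd.DataFrame(
            {"log2fc": log2fc, "p": p},
            index=[f"G{i}" for i in range(1, len(log2fc) + 1)],
        )

    def test_thresholds(self):
        # FC exactly 2.0 with small p is called; FC 1.9 is not; p exactly
        # 0.05 is not (strict p, inclusive FC)
        recs = self._records(
            [1.0, np.log2(1.9), 2.0, -1.5], [0.01, 0.001, 0.05, 0.02]
        )
        ann = toy_annotation(list(recs.index), ["mRNA", "mRNA", "mRNA", "lncRNA"])
        de = call_differential(recs, ann, AnalysisConfig())
        assert de.records["called"].tolist() == [True, False, False, True]
        assert de.dems_up == ["G1"] and de.dels_down == ["G4"]

    def test_direction_matches_sign(self):
        recs = self._records([0.5, -0.5], [0.5, 0.5])
        ann = toy_annotation(["G1", "G2"], ["mRNA", "mRNA"])
        de = call_differential(recs, ann, AnalysisConfig())
        assert de.records["direction"].tolist() == ["up", "down"]

    def test_unannotated_gene_rejected(self):
        recs = self._records([1.0], [0.01])
        ann = toy_annotation(["OTHER"], ["mRNA"])
        with pytest.raises(ValidationError):
            call_differential(recs, ann, AnalysisConfig())


class TestChromosomeSummary:
    def test_counting_and_conservation(self):
        genes = [f"G{i}" for i in range(1, 6)]
        recs = pd.DataFrame(
            {"log2fc": [2, 2, 2, -2, -2], "p": [0.01] * 5}, index=genes
        )
        ann = toy_annotation(
            genes, ["mRNA"] * 5, chroms=["chr1", "chr1", "chr1", "chr2", "chr2"]
        )
        de = call_differential(recs, ann, AnalysisConfig())
        table = summarize_by_chromosome(de, ann)
        up1 = table.query("chrom == 'chr1' and biotype == 'mRNA' and direction == 'up'")
        down2 = table.query("chrom == 'chr2' and biotype == 'mRNA' and direction == 'down'")
        assert int(up1["count"].iloc[0]) == 3
        assert int(down2["count"].iloc[0]) == 2
        assert int(table["count"].sum()) == 5

    def test_empty_de_list_all_zero(self):
        genes = ["G1", "G2"]
        recs = pd.DataFrame({"log2fc": [0.1, 0.2], "p": [0.9, 0.8]}, index=genes)
        ann = toy_annotation(genes, ["mRNA", "lncRNA"])
        de = call_differential(recs, ann, AnalysisConfig())
        table = summarize_by_chromosome(de, ann)
        assert int(table["count"].sum()) == 0
        assert set(table["chrom"]) == {"chr1"}


class TestCountSummary:
    def test_additivity(self):
        table = count_summary(10, 20, 3, 4).set_index("type")
        assert table.at["mRNA", "number"] == 30
        assert table.at["lncRNA", "number"] == 7
        assert table.at["Total", "number"] == 37
        assert table.at["Total", "up"] == 13 and table.at["Total", "down"] == 24
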