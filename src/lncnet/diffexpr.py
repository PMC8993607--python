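"""Paired empirical-Bayes moderated t-test and differential calling.

With only three tumor/normal pairs, the per-gene variance of the paired
log2 ratios is estimated on 2 degrees of freedom and an ordinary t-test is
hopelessly unstable. The moderated t shrinks each gene's variance toward a
prior estimated from all genes: assuming s_g^2 | sigma_g^2 follows a scaled
chi-square on d_g df and sigma_g^(-2) a scaled chi-square prior with
hyperparameters (d0, s0^2), the posterior variance is

    s_tilde_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

and t_g = mean(d_g) / (s_tilde_g / sqrt(n)) follows a t-distribution on
d0 + d_g df under the null. (d0, s0^2) are estimated by moment matching on
log s_g^2, inverting the trigamma function with Newton's method.
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import (
    BIOTYPE_LNCRNA,
    BIOTYPE_MRNA,
    AnalysisConfig,
    ExpressionMatrix,
    GeneAnnotationTable,
    ValidationError,
)


def paired_log_ratios(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene tumor minus normal log2 ratios; one column per pair."""
    pairs = matrix.pairs()
    data = {
        pid: matrix.values[t].to_numpy() - matrix.values[n].to_numpy()
        for pid, t, n in pairs
    }
    return pd.DataFrame(data, index=matrix.values.index)


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        raise ValidationError("trigamma inverse needs a positive argument")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


@dataclasses.dataclass(frozen=True)
class VariancePrior:
    d0: float  # prior degrees of freedom; may be inf
    s0_sq: float  # prior variance


def estimate_variance_prior(s2: np.ndarray, df: int) -> VariancePrior:
    """Moment-match (d0, s0^2) from the observed per-gene variances.

    Uses the log-variance representation: log s_g^2 is distributed as
    log sigma^2 + log chi^2_d/d; matching the mean and excess variance of
    log s_g^2 against digamma/trigamma identities yields d0. When the
    observed spread of log s_g^2 is no larger than chi-square sampling
    noise alone, the moment equation has no positive solution and the
    prior is degenerate (d0 = inf: every variance shrunk to s0^2).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        pooled = float(s2.mean()) if s2.size else 0.0
        return VariancePrior(math.inf, pooled)
    z = np.log(s2[ok])
    e = z - float(special.digamma(df / 2.0)) + math.log(df / 2.0)
    e_mean = float(e.mean())
    n = len(e)
    excess = float(((e - e_mean) ** 2).sum() / (n - 1)) - float(
        special.polygamma(1, df / 2.0)
    )
    if excess <= 0:
        return VariancePrior(math.inf, float(math.exp(e_mean)))
    d0 = 2.0 * trigamma_inverse(excess)
    s0_sq = math.exp(
        e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
    )
    return VariancePrior(d0, s0_sq)


def moderated_t(ratios: pd.DataFrame, d0: float | None = None) -> pd.DataFrame:
    """Moderated one-sample t on paired log ratios.

    Returns a frame indexed by gene with columns ``log2fc`` (mean ratio),
    ``s2`` (sample variance), ``t``, ``df`` (total = d0 + d_g) and the
    two-sided ``p``. Pass ``d0=0`` to recover the ordinary t-test or
    ``d0=inf`` for complete shrinkage; by default the prior is estimated.
    The hyperparameters are attached as ``result.attrs['d0']`` and
    ``result.attrs['s0_sq']``.
    """
    n = ratios.shape[1]
    if n < 2:
        raise ValidationError("need >= 2 pairs for a paired t-test")
    if ratios.shape[0] < 2 and d0 is None:
        raise ValidationError("need >= 2 genes to estimate the variance prior")
    arr = ratios.to_numpy(dtype=float)
    mean = arr.mean(axis=1)
    s2 = arr.var(axis=1, ddof=1)
    dg = n - 1
    if d0 is None:
        prior = estimate_variance_prior(s2, dg)
    else:
        if d0 < 0:
            raise ValidationError("d0 must be non-negative")
        s0 = float(np.mean(s2[s2 > 0])) if (s2 > 0).any() else 0.0
        prior = VariancePrior(float(d0), s0)
    if math.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0_sq)
        df_total = np.full_like(s2, math.inf)
    else:
        s2_post = (prior.d0 * prior.s0_sq + dg * s2) / (prior.d0 + dg)
        df_total = np.full_like(s2, prior.d0 + dg)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(s2_post / n)
    # degenerate genes: zero posterior variance
    zero = s2_post == 0
    t[zero & (mean == 0)] = 0.0
    t[zero & (mean > 0)] = math.inf
    t[zero & (mean < 0)] = -math.inf
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    p[t == 0] = 1.0
    out = pd.DataFrame(
        {"log2fc": mean, "s2": s2, "t": t, "df": df_total, "p": p},
        index=ratios.index,
    )
    out.attrs["d0"] = prior.d0
    out.attrs["s0_sq"] = prior.s0_sq
    return out


@dataclasses.dataclass
class DEResults:
    """Differential-expression records with DEM/DEL accessors."""

    records: pd.DataFrame  # gene-indexed: biotype, log2fc, s2, t, df, p, direction, called

    def _ids(self, biotype: str, direction: str | None = None) -> list[str]:
        r = self.records
        mask = r["called"] & (r["biotype"] == biotype)
        if direction is not None:
            mask &= r["direction"] == direction
        return list(r.index[mask])

    @property
    def dems(self) -> list[str]:
        return self._ids(BIOTYPE_MRNA)

    @property
    def dels(self) -> list[str]:
        return self._ids(BIOTYPE_LNCRNA)

    @property
    def dems_up(self) -> list[str]:
        return self._ids(BIOTYPE_MRNA, "up")

    @property
    def dems_down(self) -> list[str]:
        return self._ids(BIOTYPE_MRNA, "down")

    @property
    def dels_up(self) -> list[str]:
        return self._ids(BIOTYPE_LNCRNA, "up")

    @property
    def dels_down(self) -> list[str]:
        return self._ids(BIOTYPE_LNCRNA, "down")


def call_differential(
    stats_frame: pd.DataFrame,
    annotation: GeneAnnotationTable,
    config: AnalysisConfig,
) -> DEResults:
    """Apply the dual threshold: |linear FC| >= fc_threshold (inclusive)
    and p < p_threshold (strict), then split records by biotype."""
    missing = [g for g in stats_frame.index if g not in annotation]
    if missing:
        raise ValidationError(f"genes missing from annotation: {missing[:5]}")
    biotype = annotation.table.loc[stats_frame.index, "biotype"]
    records = stats_frame.copy()
    records["biotype"] = biotype
    records["direction"] = np.where(records["log2fc"] > 0, "up", "down")
    records["called"] = (
        (records["log2fc"].abs() >= config.log2fc_threshold)
        & (records["p"] < config.p_threshold)
    )
    return DEResults(records)


def differential_expression(
    matrix: ExpressionMatrix,
    annotation: GeneAnnotationTable,
    config: AnalysisConfig,
) -> DEResults:
    """paired ratios -> moderated t -> threshold calling, in one step."""
    return call_differential(moderated_t(paired_log_ratios(matrix)), annotation, config)


def summarize_by_chromosome(
    de: DEResults, annotation: GeneAnnotationTable
) -> pd.DataFrame:
    """Counts of called genes per chromosome x biotype x direction.

    Chromosomes present in the annotation but without any differential
    gene appear with zero counts; the grand total equals the number of
    called genes.
    """
    called = de.records[de.records["called"]]
    chrom = annotation.table.loc[called.index, "chrom"]
    idx = pd.MultiIndex.from_product(
        [annotation.chromosomes, [BIOTYPE_MRNA, BIOTYPE_LNCRNA], ["up", "down"]],
        names=["chrom", "biotype", "direction"],
    )
    counts = (
        pd.DataFrame(
            {"chrom": chrom, "biotype": called["biotype"], "direction": called["direction"]}
        )
        .groupby(["chrom", "biotype", "direction"], observed=False)
        .size()
        .reindex(idx, fill_value=0)
        .rename("count")
        .reset_index()
    )
    return counts


def count_summary(
    dem_up: int, dem_down: int, del_up: int, del_down: int
) -> pd.DataFrame:
    """Assemble the standard DE count table (per class + grand totals).

    Rows: mRNA, lncRNA, Total; columns: number (= up + down), up, down.
    """
    rows = [
        ("mRNA", dem_up + dem_down, dem_up, dem_down),
        ("lncRNA", del_up + del_down, del_up, del_down),
        ("Total", dem_up + dem_down + del_up + del_down,
         dem_up + del_up, dem_down + del_down),
    ]
    return pd.DataFrame(rows, columns=["type", "number", "up", "down"])
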