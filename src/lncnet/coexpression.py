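"""DEL-DEM Pearson co-expression network.

Correlations are computed across all samples (both conditions pooled — with
three pairs per condition there is no usable within-condition sample size),
and an edge is retained only when |r| strictly exceeds the PCC threshold
AND its two-sided correlation p-value is strictly below the p threshold.
At n = 6 samples the p criterion (|r| > ~0.811) is stricter than the
r > 0.7 criterion, so both filters are applied explicitly.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AnalysisConfig, ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation of two equal-length vectors (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("pearson_r needs two equal-length 1-D vectors")
    if len(x) < 3:
        raise ValidationError("pearson_r needs n >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise ValidationError("correlation undefined for a constant vector")
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def corr_pvalue(r: float, n: int) -> float:
    """Two-sided p for a Pearson r on n samples, via t = r*sqrt(n-2)/sqrt(1-r^2)
    on n-2 degrees of freedom. |r| = 1 maps to the smallest positive float."""
    if n < 3:
        raise ValidationError("correlation p-value needs n >= 3")
    if abs(r) > 1:
        raise ValidationError("|r| cannot exceed 1")
    if abs(r) == 1.0:
        return float(np.finfo(float).tiny)
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return float(np.clip(p, np.finfo(float).tiny, 1.0))


def min_significant_r(n: int, alpha: float = 0.05) -> float:
    """Smallest |r| whose two-sided p is below alpha at sample size n."""
    if n < 3:
        raise ValidationError("needs n >= 3")
    t_crit = stats.t.isf(alpha / 2.0, n - 2)
    return float(t_crit / np.sqrt(t_crit**2 + n - 2))


def build_coexpression_network(
    matrix: ExpressionMatrix,
    del_ids: list[str],
    dem_ids: list[str],
    config: AnalysisConfig,
) -> pd.DataFrame:
    """All (DEL, DEM) pairs passing both the |r| and the p filter.

    Returns a frame with columns ``lncrna, mrna, r, p, n`` sorted
    lexicographically by (lncrna, mrna). Genes with constant expression are
    skipped with a logged warning. An empty DEL or DEM list yields an empty
    network (warning, not an error).
    """
    columns = ["lncrna", "mrna", "r", "p", "n"]
    if not del_ids or not dem_ids:
        logger.warning("empty DEL or DEM list: co-expression network is empty")
        return pd.DataFrame(columns=columns)
    missing = [g for g in [*del_ids, *dem_ids] if g not in matrix.values.index]
    if missing:
        raise ValidationError(f"genes absent from expression matrix: {missing[:5]}")
    n = len(matrix.sample_ids)

    def _standardize(ids: list[str]) -> tuple[list[str], np.ndarray]:
        arr = matrix.values.loc[ids].to_numpy(dtype=float)
        centered = arr - arr.mean(axis=1, keepdims=True)
        norms = np.sqrt((centered**2).sum(axis=1))
        keep = norms > 0
        for g, ok in zip(ids, keep):
            if not ok:
                logger.warning("gene %s has constant expression; skipped", g)
        kept = [g for g, ok in zip(ids, keep) if ok]
        return kept, centered[keep] / norms[keep, None]

    dels, zl = _standardize(list(del_ids))
    dems, zm = _standardize(list(dem_ids))
    if not dels or not dems:
        return pd.DataFrame(columns=columns)
    r = np.clip(zl @ zm.T, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = np.clip(2.0 * stats.t.sf(np.abs(t), n - 2), np.finfo(float).tiny, 1.0)
    mask = (np.abs(r) > config.pcc_threshold) & (p < config.coexp_p_threshold)
    li, mi = np.nonzero(mask)
    edges = pd.DataFrame(
        {
            "lncrna": [dels[i] for i in li],
            "mrna": [dems[j] for j in mi],
            "r": r[li, mi],
            "p": p[li, mi],
            "n": n,
        }
    )
    return edges.sort_values(["lncrna", "mrna"], kind="mergesort").reset_index(drop=True)


def coexpressed_partners(edges: pd.DataFrame) -> dict[str, set[str]]:
    """lncRNA id -> set of co-expressed mRNA ids."""
    out: dict[str, set[str]] = {}
    for lnc, grp in edges.groupby("lncrna"):
        out[str(lnc)] = set(grp["mrna"])
    return out
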