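"""Core in-memory containers shared by every pipeline stage.

The pipeline operates on three kinds of objects: a log2 expression matrix
with paired tumor/normal sample metadata, a gene annotation table carrying
biotype (mRNA vs lncRNA) and genomic intervals, and named gene-set
collections (functional terms, TF target sets). All are thin, validated
wrappers around pandas structures.
"""
from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Iterator

import numpy as np
import pandas as pd

TUMOR = "tumor"
NORMAL = "normal"
CONDITIONS = (TUMOR, NORMAL)
BIOTYPE_MRNA = "mRNA"
BIOTYPE_LNCRNA = "lncRNA"
VALID_BIOTYPES = frozenset({BIOTYPE_MRNA, BIOTYPE_LNCRNA})
VALID_STRANDS = frozenset({"+", "-", "."})
VALID_FLAGS = frozenset({"P", "M", "A"})


class ValidationError(ValueError):
    """Raised when an input object violates a structural invariant."""


@dataclasses.dataclass
class ExpressionMatrix:
    """Log2 intensities, genes x samples, with paired-sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.
    sample_meta
        DataFrame indexed by sample id with columns ``pair_id`` and
        ``condition`` (``tumor`` or ``normal``). Every pair id must occur
        exactly once per condition.
    flags
        Optional per-cell detection calls ('P'resent / 'M'arginal /
        'A'bsent), same shape and labels as ``values``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    flags: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if v.columns.has_duplicates:
            raise ValidationError("duplicate sample ids")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.isfinite(arr).all():
            g, s = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite value at gene {v.index[g]!r}, sample {v.columns[s]!r}"
            )
        meta = self.sample_meta
        missing = [s for s in v.columns if s not in meta.index]
        if missing:
            raise ValidationError(f"samples missing from metadata: {missing}")
        meta = meta.loc[list(v.columns)]
        bad = set(meta["condition"]) - set(CONDITIONS)
        if bad:
            raise ValidationError(f"unknown condition labels: {sorted(bad)}")
        counts = meta.groupby(["pair_id", "condition"], observed=True).size()
        if (counts != 1).any():
            offender = counts[counts != 1].index[0]
            raise ValidationError(
                f"pair {offender[0]!r} has {counts[offender]} {offender[1]} samples "
                "(expected exactly 1 per condition)"
            )
        per_pair = meta.groupby("pair_id")["condition"].nunique()
        if (per_pair != 2).any():
            raise ValidationError(
                f"pair {per_pair[per_pair != 2].index[0]!r} lacks one condition"
            )
        self.sample_meta = meta
        if self.flags is not None:
            f = self.flags
            if list(f.index) != list(v.index) or list(f.columns) != list(v.columns):
                raise ValidationError("flags must share the gene/sample labels of values")
            bad_flags = set(np.unique(f.to_numpy().astype(str))) - VALID_FLAGS
            if bad_flags:
                raise ValidationError(f"unknown detection flags: {sorted(bad_flags)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_pairs(self) -> int:
        return self.sample_meta["pair_id"].nunique()

    def samples_for(self, condition: str) -> list[str]:
        meta = self.sample_meta
        return list(meta.index[meta["condition"] == condition])

    def pairs(self) -> list[tuple[str, str, str]]:
        """(pair_id, tumor_sample, normal_sample), sorted by pair id."""
        meta = self.sample_meta
        out = []
        for pid, grp in meta.groupby("pair_id"):
            t = grp.index[grp["condition"] == TUMOR][0]
            n = grp.index[grp["condition"] == NORMAL][0]
            out.append((str(pid), t, n))
        return sorted(out)

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(gene_ids)
        return ExpressionMatrix(
            self.values.loc[ids],
            self.sample_meta.copy(),
            None if self.flags is None else self.flags.loc[ids],
        )


@dataclasses.dataclass
class GeneAnnotationTable:
    """Per-gene biotype and genomic interval (0-based, half-open)."""

    table: pd.DataFrame  # index: gene id; columns: chrom, start, end, biotype, strand

    def __post_init__(self) -> None:
        t = self.table
        required = {"chrom", "start", "end", "biotype", "strand"}
        missing = required - set(t.columns)
        if missing:
            raise ValidationError(f"annotation missing columns: {sorted(missing)}")
        if t.index.has_duplicates:
            dups = t.index[t.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids in annotation: {dups[:5]}")
        if (t["start"] < 0).any():
            raise ValidationError("negative start coordinate")
        if (t["end"] <= t["start"]).any():
            gene = t.index[t["end"] <= t["start"]][0]
            raise ValidationError(f"empty or inverted interval for gene {gene!r}")
        bad_bt = set(t["biotype"]) - VALID_BIOTYPES
        if bad_bt:
            raise ValidationError(f"unknown biotype tokens: {sorted(bad_bt)}")
        bad_strand = set(t["strand"]) - VALID_STRANDS
        if bad_strand:
            raise ValidationError(f"unknown strand tokens: {sorted(bad_strand)}")

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.table.index

    def __len__(self) -> int:
        return len(self.table)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def biotype_of(self, gene_id: str) -> str:
        try:
            return str(self.table.at[gene_id, "biotype"])
        except KeyError:
            raise ValidationError(f"gene {gene_id!r} not annotated") from None

    def ids_of_biotype(self, biotype: str) -> list[str]:
        t = self.table
        return list(t.index[t["biotype"] == biotype])

    def interval(self, gene_id: str) -> tuple[str, int, int]:
        if gene_id not in self.table.index:
            raise ValidationError(f"gene {gene_id!r} not annotated")
        row = self.table.loc[gene_id]
        return str(row["chrom"]), int(row["start"]), int(row["end"])

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.table["chrom"].unique())


@dataclasses.dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    members: frozenset[str]
    category: str

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.set_id!r} is empty")


class GeneSetCollection:
    """Named gene sets with a category label per set (terms or TF targets)."""

    def __init__(self, sets: Iterable[GeneSet]):
        self._sets: dict[str, GeneSet] = {}
        for s in sets:
            if s.set_id in self._sets:
                raise ValidationError(f"duplicate set id {s.set_id!r}")
            self._sets[s.set_id] = s

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._sets.values())

    def __getitem__(self, set_id: str) -> GeneSet:
        return self._sets[set_id]

    def __contains__(self, set_id: str) -> bool:
        return set_id in self._sets

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self._sets == other._sets

    @property
    def set_ids(self) -> list[str]:
        return list(self._sets)

    @property
    def categories(self) -> list[str]:
        return sorted({s.category for s in self})

    def by_category(self, category: str) -> list[GeneSet]:
        return [s for s in self if s.category == category]

    def all_members(self) -> set[str]:
        out: set[str] = set()
        for s in self:
            out |= s.members
        return out


@dataclasses.dataclass
class AnalysisConfig:
    """Thresholds and list sizes for every stage of the pipeline.

    Defaults follow the study design: linear fold change >= 2 and p < 0.05
    for differential calls, |PCC| > 0.7 with correlation p < 0.05 for
    co-expression, a symmetric 100 kb cis window, a pooled top-500
    prediction list, and top-100 / top-10 network cutoffs.
    """

    fc_threshold: float = 2.0
    p_threshold: float = 0.05
    pcc_threshold: float = 0.7
    coexp_p_threshold: float = 0.05
    cis_window: int = 100_000
    top_predictions: int = 500
    top_tf_pairs: int = 100
    top_triples: int = 10
    seed: int = 0
    linear_input: bool = False  # if True, loaders apply log2(x + 1)
    ease: bool = False  # DAVID-style EASE score (test k-1 instead of k)

    def __post_init__(self) -> None:
        for name in ("fc_threshold", "p_threshold", "pcc_threshold",
                     "coexp_p_threshold"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.cis_window < 0 or int(self.cis_window) != self.cis_window:
            raise ValidationError("cis_window must be a non-negative integer")
        for name in ("top_predictions", "top_tf_pairs", "top_triples"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    @property
    def log2fc_threshold(self) -> float:
        return float(np.log2(self.fc_threshold))
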