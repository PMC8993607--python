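"""Readers and writers for the external file formats.

Formats handled: expression TSV (+ sample metadata TSV), BED-like gene
annotation, GMT gene sets, SIF networks with a node-attribute TSV. All
writers are deterministic: the same object always produces byte-identical
files, and ``read(write(x)) == x`` for every format.

Coordinates are 0-based half-open throughout; BED-like input is taken
as-is. Strand is read and stored but plays no role downstream.
"""
from __future__ import annotations

import os
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .containers import (
    VALID_FLAGS,
    ExpressionMatrix,
    GeneAnnotationTable,
    GeneSet,
    GeneSetCollection,
    ValidationError,
)


# ---------------------------------------------------------------- expression

def read_expression_table(
    path: str | os.PathLike,
    meta_path: str | os.PathLike,
    flags_path: str | os.PathLike | None = None,
    linear: bool = False,
) -> ExpressionMatrix:
    """Load an expression TSV plus its sample-metadata TSV.

    The matrix file has a header row of sample ids and gene ids in the
    first column. The metadata file has columns ``sample_id``, ``pair_id``,
    ``condition``. With ``linear=True`` values are transformed by
    ``log2(x + 1)`` at load (for matrices exported on the linear scale).
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    for col in values.columns:
        if not np.issubdtype(values[col].dtype, np.number):
            bad = values.index[pd.to_numeric(values[col], errors="coerce").isna()][0]
            raise ValidationError(
                f"non-numeric cell at gene {bad!r}, sample {col!r} in {path}"
            )
    if linear:
        if (values.to_numpy() < 0).any():
            raise ValidationError("negative intensities cannot be log-transformed")
        values = np.log2(values + 1.0)
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    required = {"sample_id", "pair_id", "condition"}
    if not required <= set(meta.columns):
        raise ValidationError(f"metadata must have columns {sorted(required)}")
    meta = meta.set_index("sample_id")
    flags = None
    if flags_path is not None:
        flags = pd.read_csv(flags_path, sep="\t", index_col=0, dtype=str)
        flags.index = flags.index.astype(str)
        flags.columns = flags.columns.astype(str)
    return ExpressionMatrix(values, meta, flags)


def write_expression_table(
    matrix: ExpressionMatrix,
    path: str | os.PathLike,
    meta_path: str | os.PathLike,
    flags_path: str | os.PathLike | None = None,
) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")
    meta = matrix.sample_meta.reset_index()
    meta.columns = ["sample_id", *meta.columns[1:]]
    meta.to_csv(meta_path, sep="\t", index=False)
    if flags_path is not None and matrix.flags is not None:
        matrix.flags.to_csv(flags_path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------- annotation

_ANNOT_COLS = ["chrom", "start", "end", "gene_id", "biotype", "strand"]


def read_gene_annotation(path: str | os.PathLike) -> GeneAnnotationTable:
    """Read a BED-like annotation: chrom, start, end, id, biotype, strand."""
    df = pd.read_csv(path, sep="\t", header=None, names=_ANNOT_COLS,
                     dtype={"chrom": str, "gene_id": str, "biotype": str,
                            "strand": str, "start": np.int64, "end": np.int64},
                     comment="#")
    df = df.set_index("gene_id")
    return GeneAnnotationTable(df)


def write_gene_annotation(annotation: GeneAnnotationTable, path: str | os.PathLike) -> None:
    df = annotation.table.reset_index(names="gene_id")
    df[_ANNOT_COLS].to_csv(path, sep="\t", header=False, index=False)


# ----------------------------------------------------------------------- GMT

def read_gmt(path: str | os.PathLike, category: str) -> GeneSetCollection:
    """Read a GMT file: ``set_id TAB description TAB member TAB member ...``.

    Duplicate members within a set are collapsed; a line with fewer than
    three fields (i.e. an empty set) is rejected.
    """
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields (need >= 3)"
                )
            set_id, description, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ValidationError(f"{path}:{lineno}: set {set_id!r} is empty")
            sets.append(GeneSet(set_id, description, frozenset(members), category))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for set_id in sorted(collection.set_ids):
            s = collection[set_id]
            fh.write("\t".join([s.set_id, s.description, *sorted(s.members)]) + "\n")


# ----------------------------------------------------------------------- SIF

def write_network_sif(
    network: nx.Graph,
    sif_path: str | os.PathLike,
    attr_path: str | os.PathLike | None = None,
) -> None:
    """Write a network as SIF plus a companion node-attribute TSV.

    Nodes carry a ``node_type`` attribute (lncRNA / TF / gene) and edges a
    ``relation`` attribute (coexp / cis / trans / target). Lines are sorted
    by (source, relation, target) so output is deterministic.
    """
    for node in network.nodes:
        if "\t" in str(node):
            raise ValidationError(f"node name contains a tab: {node!r}")
    lines = []
    for u, v, data in network.edges(data=True):
        relation = data.get("relation", "interacts")
        a, b = sorted((str(u), str(v)))
        lines.append((a, relation, b))
    with open(sif_path, "w") as fh:
        for a, relation, b in sorted(lines):
            fh.write(f"{a}\t{relation}\t{b}\n")
    if attr_path is not None:
        with open(attr_path, "w") as fh:
            fh.write("node\ttype\n")
            for node in sorted(network.nodes, key=str):
                fh.write(f"{node}\t{network.nodes[node].get('node_type', 'gene')}\n")


def read_network_sif(
    sif_path: str | os.PathLike,
    attr_path: str | os.PathLike | None = None,
) -> nx.Graph:
    g = nx.Graph()
    with open(sif_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            a, relation, b = line.split("\t")
            g.add_edge(a, b, relation=relation)
    if attr_path is not None:
        attrs = pd.read_csv(attr_path, sep="\t")
        for _, row in attrs.iterrows():
            if row["node"] in g:
                g.nodes[row["node"]]["node_type"] = row["type"]
            else:
                g.add_node(row["node"], node_type=row["type"])
    return g


# ---------------------------------------------------------------- frame I/O

def write_table(df: pd.DataFrame, path: str | os.PathLike, index: bool = False) -> None:
    """Deterministic TSV dump used for all result tables."""
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")
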