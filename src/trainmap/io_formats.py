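"""Readers and writers for every external representation the pipeline touches.

Expression data arrive as a tab-separated gene x sample matrix of log2
intensities plus an annotation sidecar assigning each sample a stimulus
(``trainer`` / ``comparator``), a treatment state (``baseline`` /
``stimulated``) and a replicate number.  Gene-set collections use the Broad
GMT dialect (name TAB description TAB members...), one collection per source
tag: K (KEGG), G (Gene Ontology), P (Panther), R (Reactome).  Enrichment maps
are exported as sorted node/edge TSV tables and GraphML so that repeated runs
produce byte-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

STIMULI = ("trainer", "comparator")
STATES = ("baseline", "stimulated")
SOURCE_TAGS = ("K", "G", "P", "R")

ANNOTATION_COLUMNS = ("sample_id", "stimulus", "state", "replicate")
NODE_COLUMNS = ("set", "source", "size", "score", "component")
EDGE_COLUMNS = ("set_a", "set_b", "jaccard", "overlap_coef", "overlap_score")


class FormatError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass
class ExpressionMatrix:
    """Log2 expression values for genes x annotated samples.

    ``values`` is a DataFrame indexed by gene id with one column per sample;
    ``annotations`` is indexed by sample id with columns ``stimulus``,
    ``state`` and ``replicate``.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        genes = self.values.index
        if genes.duplicated().any():
            dup = genes[genes.duplicated()][0]
            raise FormatError(f"duplicate gene id: {dup!r}")
        samples = self.values.columns
        if samples.duplicated().any():
            dup = samples[samples.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        missing = set(samples) - set(self.annotations.index)
        if missing:
            raise FormatError(
                f"sample {sorted(missing)[0]!r} has no annotation entry"
            )
        import numpy as np

        try:
            arr = self.values.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"non-numeric expression value: {exc}") from exc
        if not np.isfinite(arr).all():
            i, j = map(int, next(zip(*np.nonzero(~np.isfinite(arr)))))
            raise FormatError(
                f"non-finite value at gene {genes[i]!r}, sample {samples[j]!r}"
            )
        ann = self.annotations.loc[list(samples)]
        bad_stim = ~ann["stimulus"].isin(STIMULI)
        if bad_stim.any():
            raise FormatError(
                f"unknown stimulus {ann['stimulus'][bad_stim].iloc[0]!r}"
            )
        bad_state = ~ann["state"].isin(STATES)
        if bad_state.any():
            raise FormatError(f"unknown state {ann['state'][bad_state].iloc[0]!r}")
        if (ann["replicate"].astype(int) < 1).any():
            raise FormatError("replicate ids must be positive integers")

    # -- convenience accessors -------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, stimulus: str, state: str) -> list[str]:
        ann = self.annotations.loc[self.sample_ids]
        mask = (ann["stimulus"] == stimulus) & (ann["state"] == state)
        return list(ann.index[mask])

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(values=values, annotations=self.annotations.copy())


@dataclass(frozen=True)
class GeneSet:
    name: str
    source: str
    description: str
    members: frozenset[str]

    @property
    def qualified_name(self) -> str:
        """Collection key: sets from different sources may share a name."""
        return f"{self.name}|{self.source}"


@dataclass
class GeneSetCollection:
    """Named gene sets keyed by ``name|source`` so the four collections
    (K/G/P/R) can be merged into one family without clashes."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def add(self, gene_set: GeneSet) -> None:
        key = gene_set.qualified_name
        if key in self.sets:
            raise FormatError(f"duplicate gene set {key!r}")
        if not gene_set.members:
            raise FormatError(f"gene set {key!r} has no members")
        self.sets[key] = gene_set

    def merge(self, other: "GeneSetCollection") -> "GeneSetCollection":
        merged = GeneSetCollection(dict(self.sets))
        for gs in other.sets.values():
            merged.add(gs)
        return merged

    def members(self, key: str) -> frozenset[str]:
        return self.sets[key].members

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, key: str) -> bool:
        return key in self.sets

    def __iter__(self):
        return iter(self.sets.values())


# -- expression matrix I/O ----------------------------------------------------


def read_expression(matrix_path, annotation_path) -> ExpressionMatrix:
    """Read a tab-separated expression matrix and its annotation sidecar.

    The matrix has gene ids in the first column and sample ids in the header;
    the sidecar has columns sample_id, stimulus, state, replicate.  Sample
    order follows the matrix header.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    for col in values.columns:
        coerced = pd.to_numeric(values[col], errors="coerce")
        if coerced.isna().any():
            gene = values.index[coerced.isna()][0]
            raise FormatError(
                f"non-numeric value at gene {gene!r}, sample {col!r} "
                f"in {matrix_path}"
            )
        values[col] = coerced
    ann = pd.read_csv(annotation_path, sep="\t", dtype={"sample_id": str})
    missing_cols = set(ANNOTATION_COLUMNS) - set(ann.columns)
    if missing_cols:
        raise FormatError(f"annotation file missing columns {sorted(missing_cols)}")
    ann = ann.set_index("sample_id")
    return ExpressionMatrix(values=values, annotations=ann)


def write_expression(matrix: ExpressionMatrix, matrix_path, annotation_path) -> None:
    matrix.values.to_csv(matrix_path, sep="\t", index_label="gene_id")
    ann = matrix.annotations.loc[matrix.sample_ids]
    ann.to_csv(annotation_path, sep="\t", index_label="sample_id")


# -- GMT I/O -------------------------------------------------------------------


def read_gmt(path, source_tag: str) -> GeneSetCollection:
    """Read one Broad-dialect GMT file, tagging every set with *source_tag*.

    Members are upper-cased and deduplicated; sets left empty after cleanup
    are dropped with a warning.
    """
    if source_tag not in SOURCE_TAGS:
        raise FormatError(
            f"source tag must be one of {SOURCE_TAGS}, got {source_tag!r}"
        )
    collection = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, "
                    "expected at least 3 (name, description, members...)"
                )
            name, description, *raw_members = fields
            members = frozenset(m.upper() for m in raw_members if m.strip())
            if not members:
                logger.warning(
                    "%s:%d: dropping gene set %r with no members", path, lineno, name
                )
                continue
            collection.add(
                GeneSet(name=name, source=source_tag,
                        description=description, members=members)
            )
    return collection


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for key in sorted(collection.sets):
            gs = collection.sets[key]
            members = "\t".join(sorted(gs.members))
            fh.write(f"{gs.name}\t{gs.description}\t{members}\n")


# -- enrichment map I/O --------------------------------------------------------


def write_graph(emap, node_path, edge_path, graphml_path) -> None:
    """Export an enrichment map as node/edge TSV tables plus GraphML.

    Rows are sorted lexicographically and each edge is stored with the smaller
    set name first, so rewriting the same map yields byte-identical files.
    """
    nodes, edges = map_tables(emap)
    nodes.to_csv(node_path, sep="\t", index=False)
    edges.to_csv(edge_path, sep="\t", index=False)
    g = nx.Graph()
    for row in nodes.itertuples(index=False):
        g.add_node(row.set, source=row.source, size=int(row.size),
                   score=float(row.score), component=int(row.component))
    for row in edges.itertuples(index=False):
        g.add_edge(row.set_a, row.set_b, jaccard=float(row.jaccard),
                   overlap_coef=float(row.overlap_coef),
                   overlap_score=float(row.overlap_score))
    nx.write_graphml(g, graphml_path)


def map_tables(emap) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Canonical, sorted node and edge tables for an EnrichmentMap."""
    node_rows = []
    for name in sorted(emap.graph.nodes):
        attrs = emap.graph.nodes[name]
        node_rows.append(
            dict(set=name, source=attrs["source"], size=attrs["size"],
                 score=attrs["score"], component=attrs["component"])
        )
    edge_rows = []
    for a, b in emap.graph.edges:
        a, b = sorted((a, b))
        attrs = emap.graph.edges[a, b]
        edge_rows.append(
            dict(set_a=a, set_b=b, jaccard=attrs["jaccard"],
                 overlap_coef=attrs["overlap_coef"],
                 overlap_score=attrs["overlap_score"])
        )
    edge_rows.sort(key=lambda r: (r["set_a"], r["set_b"]))
    nodes = pd.DataFrame(node_rows, columns=NODE_COLUMNS)
    edges = pd.DataFrame(edge_rows, columns=EDGE_COLUMNS)
    return nodes, edges


def read_node_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"set": str, "source": str})


def read_edge_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"set_a": str, "set_b": str})
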