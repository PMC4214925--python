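"""Functional enrichment map: significant gene sets as nodes, membership
overlap as edges, and strongly connected components as map clusters.

Edges are weighted by the overlap score, the average of the Jaccard
coefficient |A∩B|/|A∪B| and the overlap coefficient |A∩B|/min(|A|,|B|).
Components are found with Tarjan's single-pass low-link algorithm on the
directed graph obtained by replacing each undirected edge with two opposed
arcs; under this symmetrization the strongly connected components coincide
with the connected components, which is the only well-defined reading of
"strongly connected" on an undirected similarity graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .io_formats import GeneSetCollection

DEFAULT_EDGE_THRESHOLD = 0.25


def _require_nonempty(a: frozenset, b: frozenset) -> None:
    if not a or not b:
        raise ValueError("overlap metrics are undefined for empty sets")


def jaccard(a, b) -> float:
    """|a∩b| / |a∪b| for non-empty sets."""
    a, b = frozenset(a), frozenset(b)
    _require_nonempty(a, b)
    return len(a & b) / len(a | b)


def overlap_coef(a, b) -> float:
    """|a∩b| / min(|a|, |b|) for non-empty sets."""
    a, b = frozenset(a), frozenset(b)
    _require_nonempty(a, b)
    return len(a & b) / min(len(a), len(b))


def overlap_score(a, b) -> float:
    """Average of the Jaccard and overlap coefficients; the edge weight."""
    a, b = frozenset(a), frozenset(b)
    _require_nonempty(a, b)
    return (jaccard(a, b) + overlap_coef(a, b)) / 2.0


@dataclass
class EnrichmentMap:
    """Graph of significant gene sets with overlap-scored edges.

    Node attributes: source tag, size (universe-intersected member count),
    score (-log10 p), component id.  Edge attributes: jaccard, overlap_coef,
    overlap_score.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def components(self) -> dict[str, int]:
        return {n: self.graph.nodes[n]["component"] for n in self.graph.nodes}

    def component_members(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for node, cid in self.components.items():
            out.setdefault(cid, set()).add(node)
        return out

    def n_components(self) -> int:
        return len(set(self.components.values()))


def tarjan_components(nodes, edges) -> dict:
    """Strongly connected components via iterative Tarjan's algorithm.

    The undirected input is symmetrized into a digraph (each edge becomes two
    opposed arcs) before the single-pass low-link computation, so the SCCs
    equal the connected components.  Component ids are renumbered 0, 1, ... by
    the smallest node name in each component for determinism.  Self-loops are
    rejected; the implementation is iterative, so deep graphs cannot hit the
    recursion limit.
    """
    nodes = list(nodes)
    adjacency: dict = {v: [] for v in nodes}
    for a, b in edges:
        if a == b:
            raise ValueError(f"self-loop on node {a!r}")
        if a not in adjacency or b not in adjacency:
            missing = a if a not in adjacency else b
            raise ValueError(f"edge endpoint {missing!r} is not a node")
        adjacency[a].append(b)
        adjacency[b].append(a)

    index: dict = {}
    lowlink: dict = {}
    on_stack: dict = {}
    stack: list = []
    counter = 0
    raw_components: list[list] = []

    for root in nodes:
        if root in index:
            continue
        # explicit call stack of (node, iterator over its successors)
        work = [(root, iter(adjacency[root]))]
        index[root] = lowlink[root] = counter
        counter += 1
        stack.append(root)
        on_stack[root] = True
        while work:
            v, successors = work[-1]
            advanced = False
            for w in successors:
                if w not in index:
                    index[w] = lowlink[w] = counter
                    counter += 1
                    stack.append(w)
                    on_stack[w] = True
                    work.append((w, iter(adjacency[w])))
                    advanced = True
                    break
                if on_stack.get(w, False):
                    lowlink[v] = min(lowlink[v], index[w])
            if advanced:
                continue
            work.pop()
            if work:
                parent = work[-1][0]
                lowlink[parent] = min(lowlink[parent], lowlink[v])
            if lowlink[v] == index[v]:
                component = []
                while True:
                    w = stack.pop()
                    on_stack[w] = False
                    component.append(w)
                    if w == v:
                        break
                raw_components.append(component)

    ordered = sorted(raw_components, key=lambda comp: min(map(str, comp)))
    labels: dict = {}
    for cid, comp in enumerate(ordered):
        for v in comp:
            labels[v] = cid
    return labels


def build_map(
    results: pd.DataFrame,
    collection: GeneSetCollection,
    universe,
    edge_threshold: float = DEFAULT_EDGE_THRESHOLD,
) -> EnrichmentMap:
    """Assemble the enrichment map from an enrichment result table.

    Only significant sets become nodes.  Edges join every node pair sharing
    at least one universe-intersected member whose overlap score reaches
    ``edge_threshold``; node size and the overlap metrics use the same
    universe-intersected memberships as the enrichment statistics.
    """
    universe_set = set(universe)
    graph = nx.Graph()
    significant = results[results["significant"]]
    memberships: dict[str, frozenset] = {}
    for row in significant.itertuples(index=False):
        if row.set not in collection:
            raise ValueError(f"result references unknown gene set {row.set!r}")
        members = frozenset(collection.members(row.set) & universe_set)
        memberships[row.set] = members
        graph.add_node(row.set, source=row.source, size=len(members),
                       score=float(row.score))
    names = sorted(memberships)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            shared = memberships[a] & memberships[b]
            if not shared:
                continue
            score = overlap_score(memberships[a], memberships[b])
            if score >= edge_threshold:
                graph.add_edge(
                    a, b,
                    jaccard=jaccard(memberships[a], memberships[b]),
                    overlap_coef=overlap_coef(memberships[a], memberships[b]),
                    overlap_score=score,
                )
    labels = tarjan_components(graph.nodes, graph.edges)
    nx.set_node_attributes(graph, labels, "component")
    return EnrichmentMap(graph=graph)
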