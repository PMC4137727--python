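"""The typed, undirected, simple association graph.

Nodes carry one of the three entity types; every edge belongs to exactly one
layer, determined by its endpoint types.  The graph keeps a per-layer edge
index so that layer-restricted operations (subgraphs, degree vectors, the
within-layer randomization of the null model) cost time proportional to the
layer, not the whole graph.
"""

from __future__ import annotations

from typing import Iterable, Iterator

from pathlib import Path

from .types import LAYERS, AssociationTable, layer_name, layer_types, validate_entity_type


class TypeConflictError(ValueError):
    """One entity id was assigned two different types."""


class TypedGraph:
    """Undirected simple graph with typed nodes and a layer partition of edges."""

    __slots__ = ("_types", "_adj", "_layer_edges")

    def __init__(self) -> None:
        self._types: dict[str, str] = {}
        self._adj: dict[str, set[str]] = {}
        self._layer_edges: dict[str, set[tuple[str, str]]] = {l: set() for l in LAYERS}

    # -- construction -------------------------------------------------------

    def add_node(self, node: str, etype: str) -> None:
        etype = validate_entity_type(etype)
        prev = self._types.get(node)
        if prev is None:
            self._types[node] = etype
            self._adj[node] = set()
        elif prev != etype:
            raise TypeConflictError(f"node {node!r} typed both {prev!r} and {etype!r}")

    def add_edge(self, a: str, type_a: str, b: str, type_b: str) -> bool:
        """Add an undirected edge; returns False if it already existed (simple graph)."""
        if a == b:
            raise ValueError(f"self-loop on {a!r} not allowed")
        self.add_node(a, type_a)
        self.add_node(b, type_b)
        if b in self._adj[a]:
            return False
        self._adj[a].add(b)
        self._adj[b].add(a)
        u, v = (a, b) if a < b else (b, a)
        self._layer_edges[layer_name(type_a, type_b)].add((u, v))
        return True

    def remove_edge(self, a: str, b: str) -> None:
        u, v = (a, b) if a < b else (b, a)
        self._adj[a].discard(b)
        self._adj[b].discard(a)
        self._layer_edges[self.layer_of(u, v)].discard((u, v))

    def copy(self) -> "TypedGraph":
        g = TypedGraph.__new__(TypedGraph)
        g._types = dict(self._types)
        g._adj = {n: set(s) for n, s in self._adj.items()}
        g._layer_edges = {l: set(s) for l, s in self._layer_edges.items()}
        return g

    # -- inspection ---------------------------------------------------------

    @property
    def nodes(self) -> dict[str, str]:
        """Mapping node id -> entity type."""
        return self._types

    def node_type(self, node: str) -> str:
        return self._types[node]

    def neighbors(self, node: str) -> set[str]:
        return self._adj[node]

    def has_node(self, node: str) -> bool:
        return node in self._types

    def has_edge(self, a: str, b: str) -> bool:
        return a in self._adj and b in self._adj[a]

    def degree(self, node: str) -> int:
        return len(self._adj[node])

    def layer_of(self, a: str, b: str) -> str:
        return layer_name(self._types[a], self._types[b])

    def edges(self, layer: str | None = None) -> Iterator[tuple[str, str]]:
        """Canonical (a < b) edge pairs, optionally restricted to one layer."""
        layers = [layer] if layer is not None else LAYERS
        for l in layers:
            yield from self._layer_edges[l]

    def layer_edge_counts(self) -> dict[str, int]:
        return {l: len(s) for l, s in self._layer_edges.items()}

    @property
    def n_nodes(self) -> int:
        return len(self._types)

    @property
    def n_edges(self) -> int:
        return sum(len(s) for s in self._layer_edges.values())

    def nodes_of_type(self, etype: str) -> list[str]:
        return [n for n, t in self._types.items() if t == etype]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TypedGraph):
            return NotImplemented
        return self._types == other._types and self._layer_edges == other._layer_edges

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TypedGraph(n_nodes={self.n_nodes}, n_edges={self.n_edges})"

    def to_networkx(self):
        """NetworkX view (node attribute ``etype``, edge attribute ``layer``)."""
        import networkx as nx

        g = nx.Graph()
        for n, t in self._types.items():
            g.add_node(n, etype=t)
        for l in LAYERS:
            for a, b in self._layer_edges[l]:
                g.add_edge(a, b, layer=l)
        return g


def build_graph(table: AssociationTable) -> TypedGraph:
    """One edge per unique association; direction and predicate are discarded.

    Nodes enter the graph only through edges, so isolated entities never
    appear.  An entity id typed inconsistently across associations aborts
    construction with the full list of offenders — node color is
    load-bearing for motif classification and must not be coerced.
    """
    assignments: dict[str, set[str]] = {}
    for a in table:
        assignments.setdefault(a.entity_a, set()).add(a.type_a)
        assignments.setdefault(a.entity_b, set()).add(a.type_b)
    conflicts = sorted(n for n, ts in assignments.items() if len(ts) > 1)
    if conflicts:
        raise TypeConflictError(
            f"{len(conflicts)} entities with conflicting types: {conflicts[:20]}"
        )
    g = TypedGraph()
    for a in table:
        g.add_edge(a.entity_a, a.type_a, a.entity_b, a.type_b)
    return g


def subgraph_by_layers(graph: TypedGraph, layers: Iterable[str]) -> TypedGraph:
    """Subgraph keeping only edges of the named layers and their endpoints."""
    layers = set(layers)
    if not layers:
        raise ValueError("at least one layer required")
    unknown = layers - set(LAYERS)
    if unknown:
        raise ValueError(f"unknown layers: {sorted(unknown)}")
    g = TypedGraph()
    for l in sorted(layers):
        ta, tb = layer_types(l)
        for a, b in graph._layer_edges[l]:
            g.add_edge(a, graph._types[a], b, graph._types[b])
    return g


def degrees(
    graph: TypedGraph,
    node_type: str | None = None,
    layer: str | None = None,
) -> dict[str, int]:
    """Degree per node, optionally filtered by node type and/or counting one layer only."""
    if layer is not None:
        deg: dict[str, int] = {n: 0 for n in graph.nodes}
        for a, b in graph.edges(layer):
            deg[a] += 1
            deg[b] += 1
    else:
        deg = {n: graph.degree(n) for n in graph.nodes}
    if node_type is not None:
        node_type = validate_entity_type(node_type)
        deg = {n: d for n, d in deg.items() if graph.node_type(n) == node_type}
    return deg


# ---------------------------------------------------------------------------
# Edge-list I/O (round-trips bit-exactly: sorted rows, fixed column order)


def write_edgelist(graph: TypedGraph, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("entity_a\ttype_a\tentity_b\ttype_b\tlayer\n")
        for a, b in sorted(graph.edges()):
            fh.write(
                f"{a}\t{graph.node_type(a)}\t{b}\t{graph.node_type(b)}\t{graph.layer_of(a, b)}\n"
            )


def read_edgelist(path: str | Path) -> TypedGraph:
    g = TypedGraph()
    with Path(path).open("r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("entity_a\t"):
            raise ValueError(f"{path}: not an edge-list file")
        for line in fh:
            a, ta, b, tb, layer = line.rstrip("\n").split("\t")
            if layer_name(ta, tb) != layer:
                raise ValueError(f"{path}: layer column contradicts endpoint types: {line!r}")
            g.add_edge(a, ta, b, tb)
    return g


def export_graphml(graph: TypedGraph, path: str | Path) -> None:
    """GraphML export for visualization tools (via networkx)."""
    import networkx as nx

    nx.write_graphml(graph.to_networkx(), str(path))
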