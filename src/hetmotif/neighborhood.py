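"""Case-study analytics on the association graph and core network.

These operators answer the questions the motif analysis raises: what does
the subnetwork spanned by one motif's matches look like, which genes do two
related diseases share, which neighbors of one disease are candidate
associations for the other (guilt by association), and what is the local
neighborhood of a hub.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

from .graph import TypedGraph
from .motifs import MotifPattern
from .types import ENTITY_TYPES, validate_entity_type


@dataclass
class PatternSubnetwork:
    """Induced subgraph on all nodes participating in any match of a pattern.

    Edges are *induced* — every association of the input graph among the
    participating nodes is included, not only the matches' own edges — so
    the per-layer edge counts describe the full local association structure
    around the motif.
    """

    pattern: MotifPattern
    graph: TypedGraph
    per_layer_edge_counts: dict[str, int]
    node_counts: dict[str, int]


def _induced(graph: TypedGraph, nodes: set[str]) -> TypedGraph:
    g = TypedGraph()
    for n in nodes:
        g.add_node(n, graph.node_type(n))
    for n in nodes:
        for nb in graph.neighbors(n):
            if nb in nodes and n < nb:
                g.add_edge(n, graph.node_type(n), nb, graph.node_type(nb))
    return g


def pattern_subnetwork(
    graph: TypedGraph,
    pattern: MotifPattern,
    matches: Sequence[tuple[str, str, str]],
) -> PatternSubnetwork:
    """Induced subnetwork of a pattern's matches with per-layer/type tallies."""
    if not matches:
        warnings.warn(f"no matches for {pattern.canonical}; empty subnetwork", stacklevel=2)
    nodes: set[str] = set()
    for trip in matches:
        if len(set(trip)) != 3:
            raise ValueError(f"match {trip} does not have 3 distinct nodes")
        nodes.update(trip)
    sub = _induced(graph, nodes)
    node_counts = {t: 0 for t in ENTITY_TYPES}
    for n in sub.nodes.values():
        node_counts[n] += 1
    return PatternSubnetwork(
        pattern=pattern,
        graph=sub,
        per_layer_edge_counts=sub.layer_edge_counts(),
        node_counts=node_counts,
    )


@dataclass
class SharedNeighborReport:
    anchor_a: str
    anchor_b: str
    neighbor_type: str
    shared: set[str]
    only_a: set[str]
    only_b: set[str]


def shared_neighbors(
    graph: TypedGraph, a: str, b: str, neighbor_type: str
) -> SharedNeighborReport:
    """Partition the type-filtered neighborhoods of two anchors into shared/only-a/only-b."""
    neighbor_type = validate_entity_type(neighbor_type)
    for node in (a, b):
        if not graph.has_node(node):
            raise KeyError(f"node {node!r} not in graph")
    if a == b:
        raise ValueError("anchors must differ")
    na = {n for n in graph.neighbors(a) if graph.node_type(n) == neighbor_type}
    nb = {n for n in graph.neighbors(b) if graph.node_type(n) == neighbor_type}
    return SharedNeighborReport(
        anchor_a=a,
        anchor_b=b,
        neighbor_type=neighbor_type,
        shared=na & nb,
        only_a=na - nb,
        only_b=nb - na,
    )


#: How prioritize_candidates orders its output (recorded in reports).
CANDIDATE_RANKING_RULE = (
    "descending number of nodes adjacent to both the candidate and the target "
    "(shared-neighbor support), then lexicographic by id"
)


def prioritize_candidates(
    graph: TypedGraph, source: str, target: str, candidate_type: str
) -> list[str]:
    """Guilt-by-association candidates: source's neighbors not yet linked to target.

    The premise requires source and target to already share at least one
    ``candidate_type`` neighbor; without that the returned list is empty
    with a warning.  Ranking follows :data:`CANDIDATE_RANKING_RULE`.
    """
    report = shared_neighbors(graph, source, target, candidate_type)
    if not report.shared:
        warnings.warn(
            f"{source!r} and {target!r} share no {candidate_type} neighbors; "
            "guilt-by-association premise unmet",
            stacklevel=2,
        )
        return []
    candidates = [c for c in report.only_a if c != target]
    support = {
        c: len(graph.neighbors(c) & graph.neighbors(target)) for c in candidates
    }
    return sorted(candidates, key=lambda c: (-support[c], c))


def ego_subnetwork(graph: TypedGraph, center: str, radius: int = 1) -> TypedGraph:
    """Induced subgraph on all nodes within ``radius`` hops of ``center``."""
    if not graph.has_node(center):
        raise KeyError(f"node {center!r} not in graph")
    if radius < 1:
        raise ValueError("radius must be >= 1")
    seen = {center}
    frontier = {center}
    for _ in range(radius):
        frontier = {nb for n in frontier for nb in graph.neighbors(n)} - seen
        if not frontier:
            break
        seen |= frontier
    return _induced(graph, seen)
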