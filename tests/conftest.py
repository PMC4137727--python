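"""Shared fixtures: small deterministic graphs and independent oracles.

The brute-force census here is deliberately independent of the package's
enumeration: it walks every C(n,3) node triple, counts induced edges by
direct adjacency lookups, and classifies with its own logic.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from hetmotif.graph import TypedGraph
from hetmotif.types import ENTITY_TYPES


def brute_force_census(graph: TypedGraph) -> dict[str, int]:
    """Oracle: classify all node triples by direct edge counting.

    Returns canonical pattern string -> count (only non-zero entries).
    """
    counts: dict[str, int] = {}
    nodes = sorted(graph.nodes)
    for u, v, w in itertools.combinations(nodes, 3):
        e = [
            (x, y) for x, y in ((u, v), (u, w), (v, w)) if y in graph.neighbors(x)
        ]
        if len(e) == 3:
            key = "tri:" + ",".join(sorted(graph.node_type(x) for x in (u, v, w)))
        elif len(e) == 2:
            # center = the node on both induced edges
            (a1, b1), (a2, b2) = e
            center = ({a1, b1} & {a2, b2}).pop()
            leaves = sorted(
                graph.node_type(x) for x in (u, v, w) if x != center
            )
            key = f"path:center={graph.node_type(center)};leaves={leaves[0]},{leaves[1]}"
        else:
            continue
        counts[key] = counts.get(key, 0) + 1
    return counts


def random_typed_graph(rng: np.random.Generator, n_max: int = 50) -> TypedGraph:
    """A random typed simple graph with mixed layers (possibly empty ones)."""
    n = int(rng.integers(5, n_max + 1))
    types = [ENTITY_TYPES[int(t)] for t in rng.integers(0, 3, size=n)]
    names = [f"n{i:03d}" for i in range(n)]
    g = TypedGraph()
    p = float(rng.uniform(0.03, 0.25))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(names[i], types[i], names[j], types[j])
    return g


@pytest.fixture
def toy_triangle() -> TypedGraph:
    """One disease-disease-gene triangle (the shared-gene disease-pair shape)."""
    g = TypedGraph()
    g.add_edge("d1", "disease", "d2", "disease")
    g.add_edge("d1", "disease", "g1", "gene")
    g.add_edge("d2", "disease", "g1", "gene")
    return g


@pytest.fixture
def disease_gene_star() -> TypedGraph:
    """Gene hub g1 linked to three diseases (three gene-centered paths)."""
    g = TypedGraph()
    for d in ("d1", "d2", "d3"):
        g.add_edge(d, "disease", "g1", "gene")
    return g


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260101)
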