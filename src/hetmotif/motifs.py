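"""Colored three-node subgraph census.

A connected three-node induced subgraph is either a *path* (two edges; its
isomorphism class is fixed by the center's type plus the unordered pair of
leaf types) or a *triangle* (three edges; fixed by the type multiset).  Over
three node colors that gives 3 x 6 = 18 path classes and C(3+2, 3) = 10
triangle classes — 28 patterns in all.

The census counts every distinct three-node set whose induced subgraph is
connected, exactly once (full enumeration; overlapping matches allowed, as
in FANMOD's frequency concept).  Counting is closed-form per center node for
paths, with a triangle correction, so a counts-only census costs roughly one
triangle enumeration — cheap enough to run on thousands of randomized
replicates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .types import ENTITY_TYPES, layer_name
from .graph import TypedGraph


@dataclass(frozen=True, order=True)
class MotifPattern:
    """Canonical colored isomorphism class of a connected 3-node graph.

    ``kind`` is ``"path"`` or ``"tri"``.  For a path, ``types`` is
    ``(center, leaf1, leaf2)`` with leaves sorted; for a triangle it is the
    sorted type triple.
    """

    kind: str
    types: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("path", "tri"):
            raise ValueError(f"bad pattern kind {self.kind!r}")
        if len(self.types) != 3:
            raise ValueError("pattern needs exactly 3 node types")

    @property
    def canonical(self) -> str:
        if self.kind == "tri":
            return "tri:" + ",".join(self.types)
        c, l1, l2 = self.types
        return f"path:center={c};leaves={l1},{l2}"

    def __str__(self) -> str:
        return self.canonical

    @property
    def required_layers(self) -> frozenset[str]:
        """Layers a graph must populate for this pattern to have any match."""
        if self.kind == "tri":
            a, b, c = self.types
            return frozenset({layer_name(a, b), layer_name(a, c), layer_name(b, c)})
        c, l1, l2 = self.types
        return frozenset({layer_name(c, l1), layer_name(c, l2)})

    @classmethod
    def triangle(cls, t1: str, t2: str, t3: str) -> "MotifPattern":
        return cls("tri", tuple(sorted((t1, t2, t3))))

    @classmethod
    def path(cls, center: str, leaf1: str, leaf2: str) -> "MotifPattern":
        return cls("path", (center,) + tuple(sorted((leaf1, leaf2))))

    @classmethod
    def from_canonical(cls, s: str) -> "MotifPattern":
        if s.startswith("tri:"):
            return cls.triangle(*s[4:].split(","))
        if s.startswith("path:center="):
            c, leaves = s[len("path:center="):].split(";leaves=")
            return cls.path(c, *leaves.split(","))
        raise ValueError(f"not a canonical pattern string: {s!r}")


def pattern_space() -> list[MotifPattern]:
    """All 28 colored classes of connected 3-node graphs, in fixed canonical order.

    Paths first (sorted by canonical string), then triangles.
    """
    paths = sorted(
        MotifPattern.path(c, l1, l2)
        for c in ENTITY_TYPES
        for l1, l2 in itertools.combinations_with_replacement(ENTITY_TYPES, 2)
    )
    tris = sorted(
        MotifPattern.triangle(*combo)
        for combo in itertools.combinations_with_replacement(ENTITY_TYPES, 3)
    )
    return paths + tris


def classify_triple(graph: TypedGraph, node_ids: Iterable[str]) -> MotifPattern | None:
    """Classify a 3-node set by its induced subgraph; None if not connected.

    Two induced edges make a path (the degree-2 node within the triple is
    the center); three make a triangle; one or zero edges are not connected.
    """
    ids = list(node_ids)
    if len(set(ids)) != 3:
        raise ValueError(f"need 3 distinct node ids, got {ids}")
    u, v, w = ids
    e_uv = graph.has_edge(u, v)
    e_uw = graph.has_edge(u, w)
    e_vw = graph.has_edge(v, w)
    n_edges = e_uv + e_uw + e_vw
    if n_edges == 3:
        return MotifPattern.triangle(*(graph.node_type(x) for x in ids))
    if n_edges == 2:
        if not e_vw:
            center, a, b = u, v, w
        elif not e_uw:
            center, a, b = v, u, w
        else:
            center, a, b = w, u, v
        return MotifPattern.path(
            graph.node_type(center), graph.node_type(a), graph.node_type(b)
        )
    return None


@dataclass
class MotifCensus:
    """Pattern -> count over all connected three-node sets of one graph.

    ``counts`` covers the full 28-pattern space (zeros included).  When the
    census is run with ``keep_matches``, ``matches`` maps each pattern to its
    node triples (sorted id tuples; for paths the center is recoverable from
    the graph).
    """

    counts: dict[MotifPattern, int]
    matches: dict[MotifPattern, list[tuple[str, str, str]]] | None = None

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, pattern: MotifPattern) -> int:
        return self.counts[pattern]


def _triangles(graph: TypedGraph):
    """Yield each triangle (u < v < w) exactly once via edge-anchored expansion."""
    for u, v in graph.edges():
        common = graph.neighbors(u) & graph.neighbors(v)
        for w in common:
            if w > v:
                yield u, v, w


def census(graph: TypedGraph, keep_matches: bool = False) -> MotifCensus:
    """Full census of connected three-node induced subgraphs.

    Triangles are enumerated once per (edge, larger common neighbor); path
    counts per pattern come from per-center neighbor-type tallies
    (``C(c_t, 2)`` or ``c_t1 * c_t2``) minus the adjacent pairs contributed
    by each triangle at each of its three corners.  With ``keep_matches``
    the paths are enumerated explicitly instead.
    """
    counts: dict[MotifPattern, int] = {p: 0 for p in pattern_space()}
    matches: dict[MotifPattern, list[tuple[str, str, str]]] | None = None
    if keep_matches:
        matches = {p: [] for p in counts}

    ntype = graph.nodes

    # triangles + the per-center correction for path counting
    for u, v, w in _triangles(graph):
        tri = MotifPattern.triangle(ntype[u], ntype[v], ntype[w])
        counts[tri] += 1
        if matches is not None:
            matches[tri].append(tuple(sorted((u, v, w))))
        if not keep_matches:
            for center, a, b in ((u, v, w), (v, u, w), (w, u, v)):
                counts[MotifPattern.path(ntype[center], ntype[a], ntype[b])] -= 1

    if keep_matches:
        for center in graph.nodes:
            nbrs = sorted(graph.neighbors(center))
            for i in range(len(nbrs)):
                for j in range(i + 1, len(nbrs)):
                    a, b = nbrs[i], nbrs[j]
                    if graph.has_edge(a, b):
                        continue
                    pat = MotifPattern.path(ntype[center], ntype[a], ntype[b])
                    counts[pat] += 1
                    matches[pat].append(tuple(sorted((center, a, b))))
    else:
        for center in graph.nodes:
            tally = {t: 0 for t in ENTITY_TYPES}
            for nb in graph.neighbors(center):
                tally[ntype[nb]] += 1
            ct = ntype[center]
            for t1, t2 in itertools.combinations_with_replacement(ENTITY_TYPES, 2):
                n = tally[t1] * (tally[t1] - 1) // 2 if t1 == t2 else tally[t1] * tally[t2]
                if n:
                    counts[MotifPattern.path(ct, t1, t2)] += n

    return MotifCensus(counts=counts, matches=matches)


# ---------------------------------------------------------------------------
# Report I/O


def write_census(c: MotifCensus, path) -> None:
    from pathlib import Path

    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("pattern\tcount\n")
        for p in pattern_space():
            fh.write(f"{p.canonical}\t{c.counts[p]}\n")


def write_matches(c: MotifCensus, path) -> None:
    from pathlib import Path

    if c.matches is None:
        raise ValueError("census was run without keep_matches")
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("pattern\tnode_a\tnode_b\tnode_c\n")
        for p in pattern_space():
            for trip in sorted(c.matches.get(p, [])):
                fh.write(f"{p.canonical}\t{trip[0]}\t{trip[1]}\t{trip[2]}\n")


def read_matches(path) -> dict[MotifPattern, list[tuple[str, str, str]]]:
    from pathlib import Path

    out: dict[MotifPattern, list[tuple[str, str, str]]] = {}
    with Path(path).open("r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("pattern\t"):
            raise ValueError(f"{path}: not a matches file")
        for line in fh:
            pat, a, b, c = line.rstrip("\n").split("\t")
            out.setdefault(MotifPattern.from_canonical(pat), []).append((a, b, c))
    return out
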