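"""The core network: the backbone aggregated from significant motif matches.

Every match of every significant pattern contributes its induced edges; the
overlap of matches stitches these into a superstructure — a subgraph of the
input network whose every edge is vouched for by at least one significant
motif instance.  Per-edge and per-node provenance (which patterns put an
element into the core) is retained for the neighborhood analytics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .graph import TypedGraph, degrees
from .motifs import MotifPattern
from .nullmodel import SignificanceResult
from .powerfit import PowerLawFit, fit_discrete_powerlaw
from .types import validate_entity_type


@dataclass
class CoreNetwork:
    graph: TypedGraph
    edge_provenance: dict[tuple[str, str], set[MotifPattern]]
    node_provenance: dict[str, set[MotifPattern]]


def aggregate_core(
    graph: TypedGraph,
    significant: Sequence[SignificanceResult],
    matches: Mapping[MotifPattern, Sequence[tuple[str, str, str]]],
) -> CoreNetwork:
    """Union of the induced edges of all matches of significant patterns.

    ``matches`` must hold the stored matches for every significant pattern
    (rerun the census with ``keep_matches`` otherwise).  Non-significant
    results in ``significant`` are ignored, so the full significance table
    can be passed as-is.
    """
    core = TypedGraph()
    edge_prov: dict[tuple[str, str], set[MotifPattern]] = {}
    node_prov: dict[str, set[MotifPattern]] = {}
    for res in significant:
        if not res.significant:
            continue
        pat = res.pattern
        if pat not in matches:
            raise ValueError(
                f"no stored matches for significant pattern {pat.canonical}; "
                "rerun census with keep_matches=True"
            )
        for trip in matches[pat]:
            for nid in trip:
                node_prov.setdefault(nid, set()).add(pat)
            for i in range(3):
                for j in range(i + 1, 3):
                    a, b = trip[i], trip[j]
                    if graph.has_edge(a, b):
                        core.add_edge(a, graph.node_type(a), b, graph.node_type(b))
                        u, v = (a, b) if a < b else (b, a)
                        edge_prov.setdefault((u, v), set()).add(pat)
    return CoreNetwork(graph=core, edge_provenance=edge_prov, node_provenance=node_prov)


@dataclass
class DegreeDistributionSummary:
    node_type: str
    histogram: dict[int, int]
    ccdf: dict[int, float]
    fit: PowerLawFit
    graph_label: str = "graph"

    @property
    def fitted_exponent(self) -> float:
        return self.fit.alpha


def _as_graph(core_or_graph: CoreNetwork | TypedGraph) -> tuple[TypedGraph, str]:
    if isinstance(core_or_graph, CoreNetwork):
        return core_or_graph.graph, "core"
    return core_or_graph, "full"


def degree_distribution(
    core_or_graph: CoreNetwork | TypedGraph, node_type: str
) -> DegreeDistributionSummary:
    """Degree histogram, CCDF and power-law exponent for one entity type.

    Accepts either the core network or the full integrated graph; the
    summary records which was used.  CCDF(d) is the fraction of nodes of the
    type with degree >= d, so it is 1.0 at the minimum observed degree and
    non-increasing.
    """
    g, label = _as_graph(core_or_graph)
    node_type = validate_entity_type(node_type)
    deg = degrees(g, node_type=node_type)
    if len(deg) < 2:
        raise ValueError(f"need >= 2 nodes of type {node_type!r}, have {len(deg)}")
    values = np.asarray(sorted(deg.values()))
    hist: dict[int, int] = {}
    for d in values.tolist():
        hist[d] = hist.get(d, 0) + 1
    n = values.size
    ccdf = {int(d): float(np.sum(values >= d)) / n for d in np.unique(values)}
    fit = fit_discrete_powerlaw(values)
    return DegreeDistributionSummary(
        node_type=node_type, histogram=hist, ccdf=ccdf, fit=fit, graph_label=label
    )


@dataclass
class HubReport:
    node_type: str
    ranked_nodes: list[tuple[str, int]]
    selection_rule: str = (
        "top-k by degree, ties broken lexicographically by id; "
        "descriptively, nodes with >= 10 links are called hubs"
    )


def hubs(
    core_or_graph: CoreNetwork | TypedGraph, node_type: str, top_k: int
) -> HubReport:
    """The top_k highest-degree nodes of one type (deterministic tie-break)."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    g, _ = _as_graph(core_or_graph)
    node_type = validate_entity_type(node_type)
    deg = degrees(g, node_type=node_type)
    if not deg:
        warnings.warn(f"no nodes of type {node_type!r} in the graph", stacklevel=2)
        return HubReport(node_type=node_type, ranked_nodes=[])
    ranked = sorted(deg.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
    return HubReport(node_type=node_type, ranked_nodes=ranked)


# ---------------------------------------------------------------------------
# I/O


def write_core(core: CoreNetwork, edge_path: str | Path, provenance_path: str | Path) -> None:
    from .graph import write_edgelist

    write_edgelist(core.graph, edge_path)
    with Path(provenance_path).open("w", encoding="utf-8") as fh:
        fh.write("entity_a\tentity_b\tpatterns\n")
        for (a, b), pats in sorted(core.edge_provenance.items()):
            fh.write(f"{a}\t{b}\t{';'.join(sorted(p.canonical for p in pats))}\n")


def write_degree_summary(summary: DegreeDistributionSummary, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(
            f"# node_type={summary.node_type} graph={summary.graph_label} "
            f"alpha={summary.fit.alpha:.4f} xmin={summary.fit.xmin} "
            f"ks={summary.fit.ks:.4f} method={summary.fit.method}\n"
        )
        fh.write("degree\tn_nodes\tccdf\n")
        for d in sorted(summary.histogram):
            fh.write(f"{d}\t{summary.histogram[d]}\t{summary.ccdf[d]:.6g}\n")


def plot_ccdf(summary: DegreeDistributionSummary, path: str | Path) -> None:
    """Log-log CCDF plot (optional; requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ds = sorted(summary.ccdf)
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.loglog(ds, [summary.ccdf[d] for d in ds], "o", ms=3)
    ax.set_xlabel("degree")
    ax.set_ylabel("CCDF")
    ax.set_title(
        f"{summary.node_type} ({summary.graph_label}); alpha={summary.fit.alpha:.2f}"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
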