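"""One-command orchestration: ingest -> filter -> build -> census -> significance -> core.

Every stage writes its artifact into the run directory and reports its
counts, so the run report doubles as a Table-1-style audit trail of the
filtering chain.  All randomness flows from one root seed.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .types import ENTITY_TYPES, LAYERS, AssociationTable
from . import associations as assoc
from .graph import TypedGraph, build_graph, subgraph_by_layers, write_edgelist
from .motifs import MotifCensus, MotifPattern, census, pattern_space, write_census, write_matches
from .nullmodel import (
    RandomizationConfig,
    SignificanceResult,
    call_significance,
    ensemble_census,
    write_significance,
)
from .core import (
    CoreNetwork,
    aggregate_core,
    degree_distribution,
    hubs,
    write_core,
    write_degree_summary,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    layer_files: dict[str, str]
    out_dir: str
    whitelist_file: str | None = None
    stoplist_file: str | None = None
    strict_parse: bool = False
    randomization: RandomizationConfig = field(default_factory=RandomizationConfig)
    alpha: float = 0.05
    min_count: int = 5
    p_mode: str = "geq"
    hub_top_k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.layer_files) - set(LAYERS)
        if unknown:
            raise ValueError(f"unknown layers in config: {sorted(unknown)}")
        # one root seed drives everything
        self.randomization.seed = self.seed

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        rand = RandomizationConfig(**raw.pop("randomization", {}))
        return cls(randomization=rand, **raw)


@dataclass
class RunReport:
    stage_counts: dict
    significance: list[SignificanceResult]
    n_significant: int
    core_summary: dict
    hub_reports: dict
    degree_fits: dict
    config_echo: dict
    version: str
    stage_seconds: dict

    # artifacts handy for downstream analysis in-process
    graph: TypedGraph | None = None
    real_census: MotifCensus | None = None
    core: CoreNetwork | None = None
    table: AssociationTable | None = None

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "stage_counts": self.stage_counts,
            "n_significant": self.n_significant,
            "significant_patterns": [
                r.pattern.canonical for r in self.significance if r.significant
            ],
            "core_summary": self.core_summary,
            "hub_reports": self.hub_reports,
            "degree_fits": self.degree_fits,
            "config": self.config_echo,
            "stage_seconds": {k: round(v, 3) for k, v in self.stage_seconds.items()},
        }


def _counts(table: AssociationTable) -> dict[str, int]:
    c = table.per_layer_counts
    c["total"] = len(table)
    return c


def run_pipeline(config: RunConfig) -> RunReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("hetmotif")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    timings: dict[str, float] = {}
    stage_counts: dict = {}

    def stage(name):
        logger.info("stage: %s", name)
        timings[name] = time.perf_counter()

    def done(name):
        timings[name] = time.perf_counter() - timings[name]

    try:
        stage("ingest")
        records = []
        n_records_per_layer: dict[str, int] = {}
        for layer, path in sorted(config.layer_files.items()):
            recs = list(
                assoc.parse_predications(path, layer_hint=layer, strict=config.strict_parse)
            )
            n_records_per_layer[layer] = len(recs)
            records.extend(recs)
        stage_counts["records"] = {
            **n_records_per_layer,
            "total": len(records),
        }
        done("ingest")

        stage("deduplicate")
        table = assoc.deduplicate(records)
        stage_counts["unique_associations"] = _counts(table)
        stage_counts["dropped_self_records"] = table.dropped_self
        done("deduplicate")

        stage("filter")
        if config.whitelist_file:
            wl = assoc.read_whitelist(config.whitelist_file)
            table = assoc.filter_by_drug_whitelist(table, wl)
            stage_counts["post_whitelist"] = _counts(table)
            table = assoc.restrict_to_derived_lists(table)
            stage_counts["post_derived_lists"] = _counts(table)
        if config.stoplist_file:
            sl = assoc.read_stoplist(config.stoplist_file)
            table = assoc.remove_stoplist_terms(table, sl)
            stage_counts["post_stoplist"] = _counts(table)
        assoc.write_table(table, out / "associations.tsv")
        done("filter")

        stage("build_graph")
        graph = build_graph(table)
        write_edgelist(graph, out / "graph.edgelist.tsv")
        stage_counts["graph"] = {
            "nodes": graph.n_nodes,
            "edges": graph.n_edges,
            **graph.layer_edge_counts(),
        }
        done("build_graph")

        stage("census")
        real = census(graph, keep_matches=True)
        write_census(real, out / "census.tsv")
        write_matches(real, out / "matches.tsv")
        stage_counts["census_total_triples"] = real.total
        done("census")

        stage("null_ensemble")
        stats = ensemble_census(graph, config.randomization)
        done("null_ensemble")

        stage("significance")
        results = call_significance(
            real, stats, min_count=config.min_count, alpha=config.alpha, p_mode=config.p_mode
        )
        write_significance(results, out / "significance.tsv")
        n_sig = sum(r.significant for r in results)
        done("significance")

        stage("core")
        core = aggregate_core(graph, results, real.matches or {})
        write_core(core, out / "core.edgelist.tsv", out / "core_provenance.tsv")
        core_summary = {
            "nodes": core.graph.n_nodes,
            "edges": core.graph.n_edges,
            **core.graph.layer_edge_counts(),
        }
        done("core")

        stage("reports")
        hub_reports = {}
        degree_fits = {}
        target = core if core.graph.n_edges else graph
        import warnings as _warnings

        for t in ENTITY_TYPES:
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                rep = hubs(target, t, config.hub_top_k)
            if rep.ranked_nodes:
                hub_reports[t] = rep.ranked_nodes
                with (out / f"hubs_{t}.tsv").open("w", encoding="utf-8") as fh:
                    fh.write("node\tdegree\n")
                    for nid, d in rep.ranked_nodes:
                        fh.write(f"{nid}\t{d}\n")
            try:
                summ = degree_distribution(target, t)
                degree_fits[t] = {
                    "alpha": summ.fit.alpha,
                    "xmin": summ.fit.xmin,
                    "ks": summ.fit.ks,
                    "graph": summ.graph_label,
                }
                write_degree_summary(summ, out / f"degree_{t}.tsv")
            except ValueError as exc:
                logger.info("degree fit skipped for %s: %s", t, exc)
        done("reports")
    except Exception as exc:
        logger.exception("pipeline aborted: %s", exc)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()

    report = RunReport(
        stage_counts=stage_counts,
        significance=results,
        n_significant=n_sig,
        core_summary=core_summary,
        hub_reports=hub_reports,
        degree_fits=degree_fits,
        config_echo={
            "seed": config.seed,
            "alpha": config.alpha,
            "min_count": config.min_count,
            "p_mode": config.p_mode,
            "n_networks": config.randomization.n_networks,
            "swaps_per_edge": config.randomization.swaps_per_edge,
            "null_mode": config.randomization.null_mode,
        },
        version=__version__,
        stage_seconds=timings,
        graph=graph,
        real_census=real,
        core=core,
        table=table,
    )
    (out / "report.yaml").write_text(
        yaml.safe_dump(report.to_dict(), sort_keys=False), encoding="utf-8"
    )
    return report


def compare_layer_censuses(
    graph: TypedGraph,
    layer_sets: list[set[str]],
    config: RandomizationConfig,
    min_count: int = 5,
    alpha: float = 0.05,
    p_mode: str = "geq",
):
    """Significance called independently on each layer-restricted subgraph.

    Returns a pandas DataFrame (pattern x network) of significance flags —
    the comparison showing that motifs of the full heterogeneous network are
    not all detectable in its single- or two-type restrictions.
    """
    import pandas as pd

    if len(layer_sets) < 2:
        raise ValueError("need at least two layer sets to compare")
    columns: dict[str, dict[str, bool]] = {}
    for ls in layer_sets:
        name = base = "+".join(sorted(ls))
        k = 2
        while name in columns:  # duplicate layer sets keep distinct columns
            name = f"{base}#{k}"
            k += 1
        sub = subgraph_by_layers(graph, ls)
        real = census(sub)
        stats = ensemble_census(sub, config)
        results = call_significance(
            real, stats, min_count=min_count, alpha=alpha, p_mode=p_mode
        )
        columns[name] = {r.pattern.canonical: r.significant for r in results}
    return pd.DataFrame(
        {name: [col[p.canonical] for p in pattern_space()] for name, col in columns.items()},
        index=[p.canonical for p in pattern_space()],
    )
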