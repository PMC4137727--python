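"""Synthetic literature-style association data with known ground truth.

The generator emulates the statistical shape of a predication corpus
extracted from biomedical literature: six association layers over the three
entity types, heavy redundancy (one entity pair asserted by many PMIDs, in
both argument orders), heavy-tailed degree structure within each layer,
contaminating generic-term nodes, and an optional excess of planted
three-node motif matches wired onto reserved nodes.  Everything it emits is
recorded in a ground-truth manifest so every pipeline stage can be audited
exactly.

Background wiring is Chung-Lu style: endpoints of a layer's edges are drawn
with probability proportional to per-node weights sampled from a discrete
power law (capped at sqrt(2m) to avoid hub saturation) or uniform weights.
Planted matches use nodes excluded from background wiring, so the planted
count is a guaranteed lower bound on the realized pattern count; the
manifest records both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .types import (
    ENTITY_TYPES,
    LAYERS,
    AssociationTable,
    UniqueAssociation,
    layer_name,
    layer_types,
)
from .graph import TypedGraph, build_graph
from .motifs import MotifPattern, census

PREDICATES = ("ASSOCIATED_WITH", "TREATS", "INTERACTS_WITH")

#: Generic stop-terms seen in literature-derived tables; extended with
#: numbered synthetic terms when more contamination is requested.
GENERIC_TERMS = (
    "protein", "gene", "homologous gene", "cells", "enzyme",
    "peptide", "dna", "rna", "antibody", "receptor",
)


@dataclass
class SyntheticConfig:
    nodes_per_type: dict[str, int]
    edges_per_layer: dict[str, int]
    redundancy: float = 1.5
    stoplist_contamination: int = 0
    planted: list[tuple[MotifPattern, int]] = field(default_factory=list)
    degree_model: str = "powerlaw"  # or "uniform"
    powerlaw_exponent: float = 2.5
    whitelist_fraction: float = 1.0
    #: wire every planted disease/gene to a whitelisted anchor drug, so that
    #: planted motifs survive the derived-list preprocessing (in the emulated
    #: corpus every analysed disease/gene is drug-connected by construction)
    anchor_planted_to_drugs: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.redundancy < 1:
            raise ValueError("redundancy must be >= 1 (mean records per association)")
        if not 0 < self.whitelist_fraction <= 1:
            raise ValueError("whitelist_fraction must be in (0, 1]")
        if self.degree_model not in ("powerlaw", "uniform"):
            raise ValueError(f"unknown degree_model {self.degree_model!r}")
        for l, m in self.edges_per_layer.items():
            ta, tb = layer_types(l)
            na, nb = self.nodes_per_type.get(ta, 0), self.nodes_per_type.get(tb, 0)
            cap = na * (na - 1) // 2 if ta == tb else na * nb
            if m > cap:
                raise ValueError(
                    f"layer {l}: {m} edges requested but at most {cap} simple edges exist"
                )

    @classmethod
    def study(cls, seed: int = 0, planted_triangles: int = 30) -> "SyntheticConfig":
        """The default synthetic study: a sparse tripartite literature network.

        300 diseases, 300 genes, 100 drugs; per-layer edge budgets in a
        literature-like ratio (disease-gene densest); power-law degree
        weights at exponent 2.5; ``planted_triangles`` excess
        disease-disease-gene triangles on reserved nodes.
        """
        return cls(
            nodes_per_type={"disease": 300, "gene": 300, "drug": 100},
            edges_per_layer={
                "disease-disease": 200,
                "disease-gene": 400,
                "disease-drug": 200,
                "drug-gene": 150,
                "drug-drug": 50,
                "gene-gene": 200,
            },
            redundancy=1.5,
            planted=[(MotifPattern.triangle("disease", "disease", "gene"), planted_triangles)],
            degree_model="powerlaw",
            powerlaw_exponent=2.5,
            whitelist_fraction=1.0,
            seed=seed,
        )


@dataclass
class GroundTruthManifest:
    """Everything a test needs to audit the generated corpus, stage by stage."""

    per_layer_records: dict[str, int]
    per_layer_unique: dict[str, int]
    n_entities_by_type: dict[str, int]
    whitelist: list[str]
    stoplist: list[str]
    planted: list[dict]
    planted_guaranteed: dict[str, int]
    planted_realized: dict[str, int]
    expected_post_whitelist: dict[str, int]
    expected_post_derived: dict[str, int]
    expected_post_stoplist: dict[str, int]
    n_nodes: int
    n_edges: int
    seed: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def write(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8")


def powerlaw_degree_sequence(n: int, exponent: float, seed: int) -> list[int]:
    """Discrete power-law sample adjusted to an even sum (graph-realizable).

    Values are drawn from the zeta (Zipf) distribution with the given
    exponent and capped at n - 1; if the sum is odd one entry is bumped by 1.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    if exponent <= 1:
        raise ValueError("exponent must be > 1")
    from scipy.stats import zipf

    rng = np.random.default_rng(seed)
    ks = zipf.rvs(exponent, size=n, random_state=rng)
    ks = np.minimum(ks, n - 1)
    if ks.sum() % 2 == 1:
        ks[int(np.argmin(ks))] += 1
    return [int(k) for k in ks]


def _layer_weights(cfg: SyntheticConfig, nodes: list[str], m: int, rng) -> np.ndarray:
    if cfg.degree_model == "uniform" or not nodes:
        return np.ones(len(nodes))
    from scipy.stats import zipf

    w = zipf.rvs(cfg.powerlaw_exponent, size=len(nodes), random_state=rng).astype(float)
    return np.minimum(w, max(3.0, np.sqrt(2.0 * max(m, 1))))


def _sample_layer_edges(
    layer: str,
    m: int,
    nodes_by_type: dict[str, list[str]],
    cfg: SyntheticConfig,
    rng,
) -> set[tuple[str, str]]:
    ta, tb = layer_types(layer)
    na, nb = nodes_by_type[ta], nodes_by_type[tb]
    if m == 0:
        return set()
    wa = _layer_weights(cfg, na, m, rng)
    pa = wa / wa.sum()
    if ta == tb:
        nb, pb = na, pa
    else:
        wb = _layer_weights(cfg, nb, m, rng)
        pb = wb / wb.sum()
    edges: set[tuple[str, str]] = set()
    attempts = 0
    limit = 500 * m + 1000
    while len(edges) < m:
        batch = min(m - len(edges) + 32, 4096)
        ia = rng.choice(len(na), size=batch, p=pa)
        ib = rng.choice(len(nb), size=batch, p=pb)
        for u, v in zip(ia.tolist(), ib.tolist()):
            a, b = na[u], nb[v]
            if a == b:
                continue
            pair = (a, b) if a < b else (b, a)
            edges.add(pair)
            if len(edges) == m:
                break
        attempts += batch
        if attempts > limit:
            raise RuntimeError(
                f"layer {layer}: could not place {m} distinct edges after {attempts} draws "
                "(layer too dense for the weight distribution)"
            )
    return edges


_PATTERN_EDGES = {
    "tri": ((0, 1), (0, 2), (1, 2)),
    "path": ((0, 1), (0, 2)),  # node 0 is the path center
}


def generate(
    config: SyntheticConfig, out_dir: str | Path
) -> tuple[dict[str, Path], GroundTruthManifest]:
    """Emit predication TSVs, whitelist, stoplist and the ground-truth manifest.

    Returns the written file paths (keyed by layer name plus ``whitelist``,
    ``stoplist``, ``manifest``) and the manifest object.  Byte-identical for
    identical config + seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xC0FFEE)))

    names = {
        t: [f"{t}{i:04d}" for i in range(config.nodes_per_type.get(t, 0))]
        for t in ENTITY_TYPES
    }
    types_of = {n: t for t, ns in names.items() for n in ns}

    # --- reserve nodes for planted matches (untouched by background wiring)
    reserved: dict[str, int] = {t: 0 for t in ENTITY_TYPES}
    planted_records: list[dict] = []
    planted_edges: set[tuple[str, str]] = set()
    for pattern, count in config.planted:
        if count < 0:
            raise ValueError("planted counts must be >= 0")
        if pattern.kind == "tri":
            node_types = list(pattern.types)
        else:
            node_types = [pattern.types[0], pattern.types[1], pattern.types[2]]
        for _ in range(count):
            trip = []
            for t in node_types:
                idx = reserved[t]
                if idx >= len(names[t]):
                    raise ValueError(
                        f"not enough {t} nodes to reserve for planted patterns"
                    )
                trip.append(names[t][idx])
                reserved[t] += 1
            for i, j in _PATTERN_EDGES[pattern.kind]:
                a, b = trip[i], trip[j]
                planted_edges.add((a, b) if a < b else (b, a))
            planted_records.append(
                {"pattern": pattern.canonical, "nodes": sorted(trip)}
            )
    planted_guaranteed: dict[str, int] = {}
    for pattern, count in config.planted:
        planted_guaranteed[pattern.canonical] = (
            planted_guaranteed.get(pattern.canonical, 0) + count
        )

    # anchor planted non-drug nodes to reserved whitelisted drugs
    anchor_drugs: list[str] = []
    planted_nondrug = sorted(
        {n for rec in planted_records for n in rec["nodes"] if types_of[n] != "drug"}
    )
    if config.anchor_planted_to_drugs and planted_nondrug:
        n_anchor = min(5, len(names["drug"]) - reserved["drug"])
        if n_anchor < 1:
            raise ValueError("no drug nodes left to anchor planted patterns to")
        anchor_drugs = names["drug"][reserved["drug"]:reserved["drug"] + n_anchor]
        reserved["drug"] += n_anchor
        for k, node in enumerate(planted_nondrug):
            d = anchor_drugs[k % n_anchor]
            planted_edges.add((node, d) if node < d else (d, node))

    background_pool = {
        t: names[t][reserved[t]:] for t in ENTITY_TYPES
    }

    # --- background edges per layer
    unique_by_layer: dict[str, set[tuple[str, str]]] = {l: set() for l in LAYERS}
    for l in LAYERS:
        m = config.edges_per_layer.get(l, 0)
        unique_by_layer[l] = _sample_layer_edges(l, m, background_pool, config, rng)
    for a, b in planted_edges:
        unique_by_layer[layer_name(types_of[a], types_of[b])].add((a, b))

    # --- generic stop-term contamination
    stoplist: list[str] = []
    for i in range(config.stoplist_contamination):
        term = GENERIC_TERMS[i] if i < len(GENERIC_TERMS) else f"generic term {i:03d}"
        gtype = ENTITY_TYPES[i % len(ENTITY_TYPES)]
        stoplist.append(term)
        types_of[term] = gtype
        n_links = int(rng.integers(1, 4))
        for _ in range(n_links):
            ptype = ENTITY_TYPES[int(rng.integers(len(ENTITY_TYPES)))]
            pool = background_pool[ptype]
            if not pool:
                continue
            partner = pool[int(rng.integers(len(pool)))]
            pair = (term, partner) if term < partner else (partner, term)
            unique_by_layer[layer_name(gtype, ptype)].add(pair)

    # --- whitelist: all planted drugs plus a fraction of the remaining drugs
    planted_drugs = sorted(
        {n for rec in planted_records for n in rec["nodes"] if types_of[n] == "drug"}
        | set(anchor_drugs)
    )
    drug_nodes = [n for n in names["drug"]]
    other_drugs = [d for d in drug_nodes if d not in set(planted_drugs)]
    n_extra = int(round(config.whitelist_fraction * len(other_drugs)))
    extra = sorted(
        (np.asarray(other_drugs)[rng.permutation(len(other_drugs))[:n_extra]]).tolist()
    ) if other_drugs else []
    whitelist = sorted(set(planted_drugs) | set(extra))

    # --- expand unique associations into redundant records and write TSVs
    paths: dict[str, Path] = {}
    per_layer_records = {l: 0 for l in LAYERS}
    per_layer_unique = {l: len(unique_by_layer[l]) for l in LAYERS}
    pmid_counter = 1
    for l in LAYERS:
        rows = []
        for a, b in sorted(unique_by_layer[l]):
            k = 1 + (int(rng.poisson(config.redundancy - 1)) if config.redundancy > 1 else 0)
            for _ in range(k):
                pred = PREDICATES[int(rng.integers(len(PREDICATES)))]
                pmid = f"{90000000 + pmid_counter}"
                pmid_counter += 1
                if rng.integers(2) == 0:
                    rows.append((a, types_of[a], pred, b, types_of[b], pmid))
                else:
                    rows.append((b, types_of[b], pred, a, types_of[a], pmid))
        order = rng.permutation(len(rows))
        per_layer_records[l] = len(rows)
        p = out_dir / f"{l}.tsv"
        with p.open("w", encoding="utf-8") as fh:
            fh.write("subject_id\tsubject_type\tpredicate\tobject_id\tobject_type\tpmid\n")
            for idx in order.tolist():
                fh.write("\t".join(rows[idx]) + "\n")
        paths[l] = p

    (out_dir / "whitelist.txt").write_text("\n".join(whitelist) + "\n", encoding="utf-8")
    (out_dir / "stoplist.txt").write_text(
        ("\n".join(stoplist) + "\n") if stoplist else "", encoding="utf-8"
    )
    paths["whitelist"] = out_dir / "whitelist.txt"
    paths["stoplist"] = out_dir / "stoplist.txt"

    # --- expected post-filter counts (direct set logic on the edge sets)
    wl = set(whitelist)
    sl = set(stoplist)
    post_wl: dict[str, set] = {}
    for l in LAYERS:
        ta, tb = layer_types(l)
        if "drug" in (ta, tb):
            post_wl[l] = {
                (a, b)
                for a, b in unique_by_layer[l]
                if all(types_of[x] != "drug" or x in wl for x in (a, b))
            }
        else:
            post_wl[l] = set(unique_by_layer[l])
    derived_genes = {
        x for a, b in post_wl["drug-gene"] for x in (a, b) if types_of[x] == "gene"
    }
    derived_diseases = {
        x for a, b in post_wl["disease-drug"] for x in (a, b) if types_of[x] == "disease"
    }
    in_derived = {"gene": derived_genes, "disease": derived_diseases}
    post_dl: dict[str, set] = {}
    for l in LAYERS:
        if l in ("gene-gene", "disease-disease", "disease-gene"):
            post_dl[l] = {
                (a, b)
                for a, b in post_wl[l]
                if all(x in in_derived[types_of[x]] for x in (a, b))
            }
        else:
            post_dl[l] = set(post_wl[l])
    post_sl = {
        l: {(a, b) for a, b in post_dl[l] if a not in sl and b not in sl}
        for l in LAYERS
    }

    # --- realized planted counts: census of the full unfiltered graph
    table = AssociationTable()
    for l in LAYERS:
        for a, b in unique_by_layer[l]:
            table.add(
                UniqueAssociation(
                    entity_a=a, type_a=types_of[a], entity_b=b, type_b=types_of[b],
                    support=1, pmids=set(),
                )
            )
    g = build_graph(table)
    c = census(g)
    planted_realized = {
        pat: c.counts[MotifPattern.from_canonical(pat)] for pat in planted_guaranteed
    }

    used = {x for l in LAYERS for a, b in unique_by_layer[l] for x in (a, b)}
    manifest = GroundTruthManifest(
        per_layer_records=per_layer_records,
        per_layer_unique=per_layer_unique,
        n_entities_by_type={
            t: len({x for x in used if types_of[x] == t}) for t in ENTITY_TYPES
        },
        whitelist=whitelist,
        stoplist=stoplist,
        planted=planted_records,
        planted_guaranteed=planted_guaranteed,
        planted_realized=planted_realized,
        expected_post_whitelist={l: len(post_wl[l]) for l in LAYERS},
        expected_post_derived={l: len(post_dl[l]) for l in LAYERS},
        expected_post_stoplist={l: len(post_sl[l]) for l in LAYERS},
        n_nodes=g.n_nodes,
        n_edges=g.n_edges,
        seed=config.seed,
    )
    manifest.write(out_dir / "manifest.yaml")
    paths["manifest"] = out_dir / "manifest.yaml"
    return paths, manifest
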