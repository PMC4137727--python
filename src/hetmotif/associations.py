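"""Ingest of predication streams and the drug-whitelist filtering strategy.

A predication file is a TSV with columns
``subject_id  subject_type  predicate  object_id  object_type  pmid``
(one row per extracted assertion; a header row is detected and skipped).
Deduplication collapses the many redundant assertions of one entity pair —
literature databases repeat the same pair across thousands of abstracts —
into a single undirected association with a support count and PMID set.

The filtering strategy mirrors the preprocessing of a literature-derived
drug-disease-gene corpus: restrict drug-touching layers to a whitelist of
approved drugs, derive the gene and disease lists from the surviving
drug-gene and drug-disease associations, restrict the homogeneous and
disease-gene layers to those lists, and finally strip generic stop-terms.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Iterator

from .types import (
    LAYERS,
    AssociationRecord,
    AssociationTable,
    UniqueAssociation,
    layer_name,
    normalize_entity,
    validate_entity_type,
)

logger = logging.getLogger(__name__)

_COLUMNS = ("subject_id", "subject_type", "predicate", "object_id", "object_type", "pmid")


class MalformedRowError(ValueError):
    """Raised in strict mode when a predication row cannot be parsed."""


def parse_predications(
    path: str | Path,
    layer_hint: str | None = None,
    strict: bool = False,
) -> Iterator[AssociationRecord]:
    """Stream :class:`AssociationRecord` objects from a TSV predication file.

    Malformed rows (wrong field count, empty ids) are logged with their line
    number and skipped, unless ``strict`` is set, in which case parsing
    aborts.  An unknown entity-type token is always an error: it indicates a
    schema problem, not line noise.  ``layer_hint``, when given, asserts that
    every record belongs to that layer.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].strip().lower() == "subject_id":
                continue  # header
            if len(fields) < 6 or not fields[0].strip() or not fields[3].strip():
                msg = f"{path.name}:{lineno}: malformed row ({len(fields)} fields)"
                if strict:
                    raise MalformedRowError(msg)
                logger.warning("skipping %s", msg)
                continue
            rec = AssociationRecord(
                subject_id=normalize_entity(fields[0]),
                subject_type=validate_entity_type(fields[1]),
                predicate=fields[2].strip(),
                object_id=normalize_entity(fields[3]),
                object_type=validate_entity_type(fields[4]),
                pmid=fields[5].strip(),
            )
            if layer_hint is not None and rec.layer != layer_hint:
                msg = f"{path.name}:{lineno}: record layer {rec.layer} != hint {layer_hint}"
                if strict:
                    raise MalformedRowError(msg)
                logger.warning("skipping %s", msg)
                continue
            yield rec


def deduplicate(records: Iterable[AssociationRecord]) -> AssociationTable:
    """Collapse a record stream into unique undirected associations per layer.

    ``(A, B)`` and ``(B, A)`` are the same association; self-assertions
    (subject == object) are dropped and counted in ``table.dropped_self``.
    Support of each association equals the number of contributing records,
    so total support + dropped_self == number of input records.
    """
    table = AssociationTable()
    for rec in records:
        if rec.subject_id == rec.object_id:
            table.dropped_self += 1
            continue
        if rec.subject_id < rec.object_id:
            a, ta, b, tb = rec.subject_id, rec.subject_type, rec.object_id, rec.object_type
        else:
            a, ta, b, tb = rec.object_id, rec.object_type, rec.subject_id, rec.subject_type
        key = (layer_name(ta, tb), a, b)
        assoc = table.get(key)
        if assoc is None:
            assoc = UniqueAssociation(entity_a=a, type_a=ta, entity_b=b, type_b=tb)
            table.add(assoc)
        assoc.support += 1
        assoc.pmids.add(rec.pmid)
    return table


def filter_by_drug_whitelist(
    table: AssociationTable, whitelist: set[str]
) -> AssociationTable:
    """Keep drug-layer associations only when every drug endpoint is whitelisted.

    Applies to the drug-drug, drug-gene and drug-disease layers; the three
    drug-free layers pass through untouched.  An empty whitelist is refused —
    it would silently empty the three drug layers.
    """
    if not whitelist:
        raise ValueError("empty drug whitelist would remove all drug-layer associations")
    wl = {normalize_entity(w) for w in whitelist}
    keep = []
    for a in table:
        drugs = [e for e, t in ((a.entity_a, a.type_a), (a.entity_b, a.type_b)) if t == "drug"]
        if all(d in wl for d in drugs):
            keep.append(a)
    out = table.subset(keep)
    logger.info(
        "drug whitelist filter: %d -> %d associations", len(table), len(out)
    )
    return out


def derived_lists(table: AssociationTable) -> tuple[set[str], set[str]]:
    """Gene and disease lists derived from the surviving drug-gene / drug-disease layers."""
    genes: set[str] = set()
    diseases: set[str] = set()
    for a in table:
        if a.layer == "drug-gene":
            genes.update(e for e, t in ((a.entity_a, a.type_a), (a.entity_b, a.type_b)) if t == "gene")
        elif a.layer == "disease-drug":
            diseases.update(
                e for e, t in ((a.entity_a, a.type_a), (a.entity_b, a.type_b)) if t == "disease"
            )
    return genes, diseases


def restrict_to_derived_lists(table: AssociationTable) -> AssociationTable:
    """Restrict gene-gene, disease-disease and disease-gene layers to the derived lists.

    Must run after the whitelist filter: the lists are read off the surviving
    drug-gene and drug-disease associations.
    """
    genes, diseases = derived_lists(table)
    in_list = {"gene": genes, "disease": diseases}
    keep = []
    for a in table:
        if a.layer in ("gene-gene", "disease-disease", "disease-gene"):
            if all(
                e in in_list[t]
                for e, t in ((a.entity_a, a.type_a), (a.entity_b, a.type_b))
            ):
                keep.append(a)
        else:
            keep.append(a)
    out = table.subset(keep)
    logger.info("derived-list restriction: %d -> %d associations", len(table), len(out))
    return out


def remove_stoplist_terms(
    table: AssociationTable, stoplist: set[str]
) -> AssociationTable:
    """Remove every association touching a stoplisted (generic) entity token.

    Matching is exact-token and case-insensitive — no substring matching, so
    ``protein`` on the stoplist does not delete ``proteinase``.
    """
    sl = {normalize_entity(s) for s in stoplist}
    removed = {l: 0 for l in LAYERS}
    keep = []
    for a in table:
        if a.entity_a in sl or a.entity_b in sl:
            removed[a.layer] += 1
        else:
            keep.append(a)
    out = table.subset(keep)
    if any(removed.values()):
        logger.info("stoplist removal per layer: %s", {k: v for k, v in removed.items() if v})
    return out


def table_stats(table: AssociationTable) -> dict:
    """Per-layer report: unique associations, supports (records), unique entities.

    Entities appearing in several layers are counted once in the overall
    total, mirroring the footnote convention of per-type statistics tables.
    """
    per_layer: dict[str, dict] = {}
    all_entities: set[str] = set()
    entities_by_type: dict[str, set[str]] = {}
    for l in LAYERS:
        assocs = table.layer(l)
        ents = set()
        for a in assocs:
            ents.add(a.entity_a)
            ents.add(a.entity_b)
            entities_by_type.setdefault(a.type_a, set()).add(a.entity_a)
            entities_by_type.setdefault(a.type_b, set()).add(a.entity_b)
        all_entities |= ents
        per_layer[l] = {
            "unique_associations": len(assocs),
            "records": sum(a.support for a in assocs),
            "unique_entities": len(ents),
        }
    return {
        "per_layer": per_layer,
        "total_unique_associations": len(table),
        "total_records": sum(a.support for a in table),
        "total_unique_entities": len(all_entities),
        "unique_entities_by_type": {t: len(s) for t, s in sorted(entities_by_type.items())},
        "dropped_self_records": table.dropped_self,
    }


# ---------------------------------------------------------------------------
# I/O


def write_table(table: AssociationTable, path: str | Path) -> None:
    """Write a unique-association table as TSV (deterministic row order)."""
    path = Path(path)
    rows = sorted(table, key=lambda a: a.key)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("layer\tentity_a\ttype_a\tentity_b\ttype_b\tsupport\tpmids\n")
        for a in rows:
            fh.write(
                f"{a.layer}\t{a.entity_a}\t{a.type_a}\t{a.entity_b}\t{a.type_b}"
                f"\t{a.support}\t{','.join(sorted(a.pmids))}\n"
            )


def read_table(path: str | Path) -> AssociationTable:
    table = AssociationTable()
    with Path(path).open("r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("layer\t"):
            raise ValueError(f"{path}: not a unique-association table")
        for line in fh:
            layer, a, ta, b, tb, support, pmids = line.rstrip("\n").split("\t")
            assoc = UniqueAssociation(
                entity_a=a,
                type_a=ta,
                entity_b=b,
                type_b=tb,
                support=int(support),
                pmids=set(pmids.split(",")) if pmids else set(),
            )
            if assoc.layer != layer:
                raise ValueError(f"{path}: layer column {layer} contradicts types")
            table.add(assoc)
    return table


def export_ntriples(table: AssociationTable, path: str | Path) -> None:
    """Export one RDF triple per unique association (N-Triples serialization).

    Subject/object URIs are minted from entity tokens, the predicate URI from
    the layer name; provenance and support are not serialized.
    """
    from urllib.parse import quote

    import rdflib

    g = rdflib.Graph()
    base = "http://hetmotif.example.org/"
    for a in sorted(table, key=lambda x: x.key):
        s = rdflib.URIRef(base + "entity/" + quote(a.entity_a, safe=""))
        p = rdflib.URIRef(base + "layer/" + quote(a.layer, safe=""))
        o = rdflib.URIRef(base + "entity/" + quote(a.entity_b, safe=""))
        g.add((s, p, o))
    g.serialize(destination=str(path), format="nt", encoding="utf-8")


def read_whitelist(path: str | Path) -> set[str]:
    """One drug token per line; blank lines and ``#`` comments ignored."""
    out = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(normalize_entity(line))
    return out


read_stoplist = read_whitelist
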