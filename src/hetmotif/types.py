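"""Shared domain vocabulary: entity types, layers, association records.

The analysis substrate is a tripartite association universe over three
biomedical entity types (drug, disease, gene).  An unordered pair of entity
types defines a *layer*; there are exactly six layers, one per row of the
association-type statistics table produced by the ingest stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

#: Closed alphabet of node colors.  Every entity has exactly one type.
ENTITY_TYPES: tuple[str, ...] = ("disease", "drug", "gene")

_ENTITY_TYPE_SET = frozenset(ENTITY_TYPES)


def validate_entity_type(token: str) -> str:
    """Return the normalized entity type, raising on anything outside the alphabet."""
    t = token.strip().lower()
    if t not in _ENTITY_TYPE_SET:
        raise ValueError(
            f"unknown entity type {token!r}; expected one of {sorted(_ENTITY_TYPE_SET)}"
        )
    return t


def layer_name(type_a: str, type_b: str) -> str:
    """Canonical layer name for an unordered pair of entity types, e.g. ``disease-gene``."""
    ta, tb = sorted((validate_entity_type(type_a), validate_entity_type(type_b)))
    return f"{ta}-{tb}"


def layer_types(layer: str) -> tuple[str, str]:
    """Inverse of :func:`layer_name`: the (sorted) endpoint-type pair of a layer."""
    parts = layer.split("-")
    if len(parts) != 2 or layer not in LAYER_SET:
        raise ValueError(f"unknown layer {layer!r}; expected one of {list(LAYERS)}")
    return parts[0], parts[1]


#: The six layers, in canonical (sorted) order.
LAYERS: tuple[str, ...] = tuple(
    sorted({layer_name(a, b) for a in ENTITY_TYPES for b in ENTITY_TYPES})
)
LAYER_SET = frozenset(LAYERS)

#: Layers with at least one drug endpoint (targets of the whitelist filter).
DRUG_LAYERS: tuple[str, ...] = tuple(l for l in LAYERS if "drug" in layer_types(l))


def normalize_entity(token: str) -> str:
    """Entity identity rule: exact token after case-folding and whitespace trimming."""
    return token.strip().casefold()


@dataclass(frozen=True)
class AssociationRecord:
    """One literature-derived subject-predicate-object assertion with provenance.

    Direction and predicate semantics are retained here for fidelity to the
    source format but are discarded at deduplication.
    """

    subject_id: str
    subject_type: str
    predicate: str
    object_id: str
    object_type: str
    pmid: str

    def __post_init__(self) -> None:
        if not self.subject_id or not self.object_id:
            raise ValueError("subject_id and object_id must be non-empty")
        validate_entity_type(self.subject_type)
        validate_entity_type(self.object_type)

    @property
    def layer(self) -> str:
        return layer_name(self.subject_type, self.object_type)


@dataclass
class UniqueAssociation:
    """A deduplicated undirected entity pair within one layer.

    ``entity_a < entity_b`` lexicographically (canonical order); ``support``
    is the number of raw records collapsed into this pair and is always at
    least ``len(pmids)`` (one PMID can assert a pair more than once).
    """

    entity_a: str
    type_a: str
    entity_b: str
    type_b: str
    support: int = 0
    pmids: set[str] = field(default_factory=set)

    @property
    def layer(self) -> str:
        return layer_name(self.type_a, self.type_b)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.layer, self.entity_a, self.entity_b)


class AssociationTable:
    """Per-layer collection of unique undirected associations with support counts."""

    def __init__(self) -> None:
        self._assoc: dict[tuple[str, str, str], UniqueAssociation] = {}
        #: number of raw records dropped because subject == object
        self.dropped_self: int = 0

    def __len__(self) -> int:
        return len(self._assoc)

    def __iter__(self) -> Iterator[UniqueAssociation]:
        return iter(self._assoc.values())

    def __contains__(self, key: tuple[str, str, str]) -> bool:
        return key in self._assoc

    def get(self, key: tuple[str, str, str]) -> UniqueAssociation | None:
        return self._assoc.get(key)

    def add(self, assoc: UniqueAssociation) -> None:
        if assoc.entity_a == assoc.entity_b:
            raise ValueError(f"self-association {assoc.entity_a!r} not allowed")
        if assoc.entity_a > assoc.entity_b:
            raise ValueError("association endpoints not in canonical order")
        if assoc.key in self._assoc:
            raise ValueError(f"duplicate canonical pair {assoc.key}")
        self._assoc[assoc.key] = assoc

    def layer(self, layer: str) -> list[UniqueAssociation]:
        return [a for a in self if a.layer == layer]

    @property
    def per_layer_counts(self) -> dict[str, int]:
        counts = {l: 0 for l in LAYERS}
        for a in self:
            counts[a.layer] += 1
        return counts

    def subset(self, keep: Iterable[UniqueAssociation]) -> "AssociationTable":
        """New table containing exactly ``keep`` (must be members of self)."""
        out = AssociationTable()
        out.dropped_self = self.dropped_self
        for a in keep:
            if a.key not in self._assoc:
                raise ValueError(f"{a.key} is not in the source table")
            out.add(a)
        return out
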