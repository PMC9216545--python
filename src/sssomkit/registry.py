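"""The SSSOM schema registry: metadata slots, controlled vocabularies and
recommended mapping predicates.

The standard defines 38 mapping-level metadata slots (four of which —
subject_id, predicate_id, object_id, match_type — are required for every
mapping) and 23 mapping-set-level slots. Thirteen slots are aligned with
external vocabularies (PAV, PROV-O, Dublin Core, RDFS); those alignments
drive the RDF serialization of mapping metadata. Ten recommended predicates,
drawn from SKOS, OWL and RDFS, are classified here by their mapping strength
(EXACT / CLOSE / RELATED / BROAD / NARROW) and by the kind of entity they
relate, which is what makes predicate-aware operations (crosswalks, OWL
export, reconciliation) possible.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

from .curie import split_curie
from .errors import SssomError

__all__ = [
    "MatchType",
    "PredicateModifier",
    "Strength",
    "SlotDefinition",
    "PredicateDescriptor",
    "MAPPING_SLOTS",
    "MAPPING_SET_SLOTS",
    "REQUIRED_MAPPING_SLOTS",
    "MULTIVALUED_SLOTS",
    "ENTITY_REFERENCE_SLOTS",
    "EXTERNAL_PROPERTIES",
    "PREDICATES",
    "CARDINALITY_VALUES",
    "registry_slots",
    "slot_definition",
    "predicate_class",
    "external_property_for",
]


class MatchType(enum.Enum):
    """How a match was established. Exactly five kinds exist."""

    Lexical = "Lexical"
    Logical = "Logical"
    HumanCurated = "HumanCurated"
    SemanticSimilarity = "SemanticSimilarity"
    Complex = "Complex"


class PredicateModifier(enum.Enum):
    """Qualifier on predicate_id; ``Not`` records an explicitly rejected mapping."""

    Not = "Not"


class Strength(enum.Enum):
    """Strength class of a mapping predicate.

    UNKNOWN marks predicates outside the recommended table: they are legal
    but downstream operations (crosswalks, reconciliation) cannot reason
    about them.
    """

    EXACT = "EXACT"
    CLOSE = "CLOSE"
    RELATED = "RELATED"
    BROAD = "BROAD"
    NARROW = "NARROW"
    UNKNOWN = "UNKNOWN"

    @property
    def inverse(self) -> "Strength":
        return _INVERSE[self]


_INVERSE = {
    Strength.EXACT: Strength.EXACT,
    Strength.CLOSE: Strength.CLOSE,
    Strength.RELATED: Strength.RELATED,
    Strength.BROAD: Strength.NARROW,
    Strength.NARROW: Strength.BROAD,
    Strength.UNKNOWN: Strength.UNKNOWN,
}


@dataclass(frozen=True)
class SlotDefinition:
    name: str
    level: str  # "mapping" | "mapping_set" | "both"
    datatype: str
    required: bool = False
    multivalued: bool = False
    external_property: Optional[str] = None


@dataclass(frozen=True)
class PredicateDescriptor:
    predicate_id: str
    strength: Strength
    entity_kind: str  # "class" | "individual" | "property" | "any"

    @property
    def inverse_strength(self) -> Strength:
        return self.strength.inverse


CARDINALITY_VALUES = ("1:1", "1:n", "n:1", "n:n")

# The 13 slots aligned with external vocabularies: 2 to PAV, 1 to PROV-O,
# the rest to Dublin Core terms and RDFS.
EXTERNAL_PROPERTIES: Dict[str, str] = {
    "author_id": "pav:authoredBy",
    "mapping_date": "pav:authoredOn",
    "reviewer_id": "prov:wasAttributedTo",
    "publication_date": "dcterms:issued",
    "license": "dcterms:license",
    "creator_id": "dcterms:creator",
    "comment": "rdfs:comment",
    "see_also": "rdfs:seeAlso",
    "subject_source": "dcterms:source",
    "object_source": "dcterms:source",
    "mapping_set_description": "dcterms:description",
    "mapping_set_id": "dcterms:identifier",
    "mapping_provider": "dcterms:publisher",
}

# name, datatype, required, multivalued — declaration order is normative for
# column order on write.
_MAPPING_SLOT_TABLE = (
    ("subject_id", "entity_reference", True, False),
    ("subject_label", "string", False, False),
    ("subject_category", "string", False, False),
    ("predicate_id", "entity_reference", True, False),
    ("predicate_label", "string", False, False),
    ("predicate_modifier", "predicate_modifier", False, False),
    ("object_id", "entity_reference", True, False),
    ("object_label", "string", False, False),
    ("object_category", "string", False, False),
    ("match_type", "match_type", True, False),
    ("mapping_cardinality", "string", False, False),
    ("author_id", "entity_reference", False, True),
    ("author_label", "string", False, False),
    ("reviewer_id", "entity_reference", False, True),
    ("reviewer_label", "string", False, False),
    ("creator_id", "entity_reference", False, True),
    ("creator_label", "string", False, False),
    ("license", "string", False, False),
    ("subject_source", "string", False, False),
    ("subject_source_version", "string", False, False),
    ("object_source", "string", False, False),
    ("object_source_version", "string", False, False),
    ("mapping_provider", "string", False, False),
    ("mapping_tool", "string", False, False),
    ("mapping_tool_version", "string", False, False),
    ("mapping_date", "date", False, False),
    ("publication_date", "date", False, False),
    ("confidence", "double", False, False),
    ("subject_match_field", "entity_reference", False, True),
    ("object_match_field", "entity_reference", False, True),
    ("match_string", "string", False, True),
    ("subject_preprocessing", "string", False, True),
    ("object_preprocessing", "string", False, True),
    ("semantic_similarity_score", "double", False, False),
    ("semantic_similarity_measure", "string", False, False),
    ("see_also", "string", False, True),
    ("other", "string", False, False),
    ("comment", "string", False, False),
)

_SET_SLOT_TABLE = (
    ("mapping_set_id", "string", True, False),
    ("mapping_set_version", "string", False, False),
    ("mapping_set_description", "string", False, False),
    ("curie_map", "prefix_map", False, False),
    ("creator_id", "entity_reference", False, True),
    ("creator_label", "string", False, False),
    ("license", "string", False, False),
    ("subject_source", "string", False, False),
    ("subject_source_version", "string", False, False),
    ("object_source", "string", False, False),
    ("object_source_version", "string", False, False),
    ("mapping_provider", "string", False, False),
    ("mapping_tool", "string", False, False),
    ("mapping_tool_version", "string", False, False),
    ("mapping_date", "date", False, False),
    ("publication_date", "date", False, False),
    ("subject_match_field", "entity_reference", False, True),
    ("object_match_field", "entity_reference", False, True),
    ("subject_preprocessing", "string", False, True),
    ("object_preprocessing", "string", False, True),
    ("see_also", "string", False, True),
    ("other", "string", False, False),
    ("comment", "string", False, False),
)


def _build() -> Tuple[Tuple[SlotDefinition, ...], Tuple[SlotDefinition, ...]]:
    mapping_names = {row[0] for row in _MAPPING_SLOT_TABLE}
    set_names = {row[0] for row in _SET_SLOT_TABLE}
    both = mapping_names & set_names

    def level_of(name: str, here: str) -> str:
        return "both" if name in both else here

    # Required flags differ per level (mapping_set_id is required only at
    # the set level); the shared-slot definitions are never required.
    mapping_defs = tuple(
        SlotDefinition(
            name=name,
            level=level_of(name, "mapping"),
            datatype=datatype,
            required=required,
            multivalued=multivalued,
            external_property=EXTERNAL_PROPERTIES.get(name),
        )
        for name, datatype, required, multivalued in _MAPPING_SLOT_TABLE
    )
    set_defs = tuple(
        SlotDefinition(
            name=name,
            level=level_of(name, "mapping_set"),
            datatype=datatype,
            required=required,
            multivalued=multivalued,
            external_property=EXTERNAL_PROPERTIES.get(name),
        )
        for name, datatype, required, multivalued in _SET_SLOT_TABLE
    )
    return mapping_defs, set_defs


MAPPING_SLOTS, MAPPING_SET_SLOTS = _build()
_BY_NAME: Dict[str, SlotDefinition] = {d.name: d for d in MAPPING_SLOTS}
for _d in MAPPING_SET_SLOTS:
    _BY_NAME.setdefault(_d.name, _d)

REQUIRED_MAPPING_SLOTS = tuple(d.name for d in MAPPING_SLOTS if d.required)
MULTIVALUED_SLOTS = frozenset(d.name for d in MAPPING_SLOTS + MAPPING_SET_SLOTS if d.multivalued)
ENTITY_REFERENCE_SLOTS = frozenset(
    d.name for d in MAPPING_SLOTS + MAPPING_SET_SLOTS if d.datatype == "entity_reference"
)


def registry_slots(level: str) -> Tuple[SlotDefinition, ...]:
    """Slot definitions for *level* ("mapping" or "mapping_set"), in
    declaration order. Slots shared by both levels appear in both views."""
    if level == "mapping":
        return MAPPING_SLOTS
    if level == "mapping_set":
        return MAPPING_SET_SLOTS
    raise SssomError(f"unknown registry level: {level!r}")


def slot_definition(name: str) -> SlotDefinition:
    try:
        return _BY_NAME[name]
    except KeyError:
        raise SssomError(f"unknown slot: {name!r}") from None


def external_property_for(slot_name: str) -> Optional[str]:
    """The external vocabulary property aligned with *slot_name*, if any."""
    return slot_definition(slot_name).external_property


PREDICATES: Dict[str, PredicateDescriptor] = {
    p.predicate_id: p
    for p in (
        PredicateDescriptor("owl:sameAs", Strength.EXACT, "individual"),
        PredicateDescriptor("owl:equivalentClass", Strength.EXACT, "class"),
        PredicateDescriptor("owl:equivalentProperty", Strength.EXACT, "property"),
        PredicateDescriptor("rdfs:subClassOf", Strength.BROAD, "class"),
        PredicateDescriptor("rdfs:subPropertyOf", Strength.BROAD, "property"),
        PredicateDescriptor("skos:relatedMatch", Strength.RELATED, "class"),
        PredicateDescriptor("skos:closeMatch", Strength.CLOSE, "class"),
        PredicateDescriptor("skos:exactMatch", Strength.EXACT, "class"),
        PredicateDescriptor("skos:narrowMatch", Strength.NARROW, "class"),
        PredicateDescriptor("skos:broadMatch", Strength.BROAD, "class"),
    )
}


def predicate_class(predicate_id: str) -> Strength:
    """Strength class of a predicate; UNKNOWN for unregistered predicates.

    Malformed CURIEs raise :class:`~sssomkit.errors.CurieError`.
    """
    split_curie(predicate_id)  # format check
    descriptor = PREDICATES.get(predicate_id)
    return descriptor.strength if descriptor else Strength.UNKNOWN
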