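"""Deterministic export of mapping sets to JSON and RDF.

Three RDF flavours are produced:

* **direct** — one plain triple per non-negated row (``S P O``). Negated
  rows are omitted: asserting ``skos:exactMatch`` for a rejected mapping
  would invert its meaning.
* **reified** — each row becomes an ``owl:Axiom`` annotation node carrying
  the annotated source/property/target plus one triple per populated
  metadata slot, using the slot's external vocabulary property (PAV,
  PROV-O, Dublin Core, RDFS) where one is registered and the native
  ``sssom:`` namespace otherwise. Negated rows are included, with the
  modifier emitted explicitly.
* **owl** — the reified graph plus ``rdf:type`` declarations for every
  mapped entity so the output is a conformant OWL ontology.

All output is sorted N-Triples, so identical sets yield identical bytes.
"""

from __future__ import annotations

import datetime as _dt
import json
from typing import Any, Dict, FrozenSet, Iterable, List, Optional, Set, Tuple, Union

from rdflib import Literal, URIRef
from rdflib.namespace import OWL, RDF, XSD

from .curie import BUILTIN_PREFIX_MAP, PrefixMap, expand, merge_prefix_maps
from .errors import KindConflict
from .model import Mapping, MappingSet
from .registry import (
    ENTITY_REFERENCE_SLOTS,
    MAPPING_SLOTS,
    PREDICATES,
    MatchType,
    PredicateModifier,
    external_property_for,
)

__all__ = ["TripleSet", "to_json", "to_rdf_direct", "to_rdf_reified", "to_owl"]

#: vocabulary prefixes used only for expanding metadata *properties*;
#: entity CURIEs still require declared prefixes.
_VOCAB = PrefixMap(
    {
        "dcterms": "http://purl.org/dc/terms/",
        "pav": "http://purl.org/pav/",
        "prov": "http://www.w3.org/ns/prov#",
        "oboInOwl": "http://www.geneontology.org/formats/oboInOwl#",
    }
)

Node = Union[URIRef, Literal]
Triple = Tuple[URIRef, URIRef, Node]


class TripleSet:
    """An order-free set of RDF triples with deterministic serialization."""

    __slots__ = ("_triples",)

    def __init__(self, triples: Iterable[Triple] = ()):
        self._triples: FrozenSet[Triple] = frozenset(triples)

    def __len__(self) -> int:
        return len(self._triples)

    def __iter__(self):
        return iter(self._triples)

    def __contains__(self, triple: Triple) -> bool:
        return triple in self._triples

    def __le__(self, other: "TripleSet") -> bool:
        return self._triples <= other._triples

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TripleSet) and self._triples == other._triples

    def __or__(self, other: "TripleSet") -> "TripleSet":
        return TripleSet(self._triples | other._triples)

    def to_ntriples(self) -> str:
        """Sorted N-Triples text (identical input -> identical bytes)."""
        lines = sorted(f"{s.n3()} {p.n3()} {o.n3()} ." for s, p, o in self._triples)
        return "".join(line + "\n" for line in lines)


# --------------------------------------------------------------------------
# JSON


def _json_scalar(value: Any) -> Any:
    if isinstance(value, (MatchType, PredicateModifier)):
        return value.value
    if isinstance(value, _dt.date):
        return value.isoformat()
    return value


def to_json(ms: MappingSet) -> str:
    """One JSON object: populated set slots, curie_map, mappings array.

    Key order is alphabetical throughout; multivalued slots are arrays.
    """
    doc: Dict[str, Any] = {}
    for name in ms.populated_set_slots():
        value = getattr(ms, name)
        if name == "curie_map":
            doc[name] = ms.curie_map.as_dict()
        elif isinstance(value, tuple):
            doc[name] = [_json_scalar(v) for v in value]
        else:
            doc[name] = _json_scalar(value)
    doc["mappings"] = [
        {
            slot: ([_json_scalar(v) for v in val] if isinstance(val := getattr(m, slot), tuple) else _json_scalar(val))
            for slot in m.populated_slots()
        }
        for m in ms.mappings
    ]
    return json.dumps(doc, sort_keys=True, indent=2) + "\n"


# --------------------------------------------------------------------------
# RDF


def _entity_pm(ms: MappingSet) -> PrefixMap:
    return ms.curie_map


def _expand_entity(curie: str, pm: PrefixMap) -> URIRef:
    return URIRef(expand(curie, pm))


def _expand_property(curie: str) -> URIRef:
    return URIRef(expand(curie, _VOCAB))


def _slot_property(slot: str) -> URIRef:
    mapped = external_property_for(slot)
    if mapped is not None:
        return _expand_property(mapped)
    return URIRef(BUILTIN_PREFIX_MAP["sssom"] + slot)


def _literal(value: Any) -> Literal:
    if isinstance(value, (MatchType, PredicateModifier)):
        return Literal(value.value)
    if isinstance(value, _dt.date):
        return Literal(value.isoformat(), datatype=XSD.date)
    if isinstance(value, float):
        return Literal(value)
    return Literal(str(value))


def to_rdf_direct(ms: MappingSet) -> TripleSet:
    """One ``S P O`` triple per non-negated row; duplicates collapse."""
    pm = _entity_pm(ms)
    triples: Set[Triple] = set()
    for m in ms.mappings:
        if m.is_negated():
            continue
        triples.add(
            (
                _expand_entity(m.subject_id, pm),
                _expand_entity(m.predicate_id, pm),
                _expand_entity(m.object_id, pm),
            )
        )
    return TripleSet(triples)


_CORE = ("subject_id", "predicate_id", "object_id")


def _axiom_node(ms: MappingSet, index: int) -> URIRef:
    # deterministic skolem IRI per row; fresh within the document
    return URIRef(f"urn:sssom:axiom:{index}")


def to_rdf_reified(ms: MappingSet) -> TripleSet:
    """owl:Axiom annotation node per row with one triple per metadata value.

    Negated rows are included; the modifier is carried as an explicit
    ``sssom:predicate_modifier`` annotation so a rejection stays visible.
    """
    pm = _entity_pm(ms)
    triples: Set[Triple] = set()
    for i, m in enumerate(ms.mappings):
        ax = _axiom_node(ms, i)
        triples.add((ax, RDF.type, OWL.Axiom))
        triples.add((ax, OWL.annotatedSource, _expand_entity(m.subject_id, pm)))
        triples.add((ax, OWL.annotatedProperty, _expand_entity(m.predicate_id, pm)))
        triples.add((ax, OWL.annotatedTarget, _expand_entity(m.object_id, pm)))
        for slot in m.populated_slots():
            if slot in _CORE:
                continue
            prop = _slot_property(slot)
            value = getattr(m, slot)
            values = value if isinstance(value, tuple) else (value,)
            for v in values:
                if slot in ENTITY_REFERENCE_SLOTS and isinstance(v, str):
                    obj: Node = _expand_entity(v, pm)
                else:
                    obj = _literal(v)
                triples.add((ax, prop, obj))
    return TripleSet(triples)


_KIND_TO_CLASS = {
    "class": OWL.Class,
    "individual": URIRef(str(OWL) + "NamedIndividual"),
    "property": OWL.ObjectProperty,
}


def to_owl(ms: MappingSet, *, skos_entity_kind: str = "class") -> TripleSet:
    """Reified output plus one type declaration per distinct mapped entity.

    The declared kind follows the predicate: equivalence/subsumption between
    classes declares ``owl:Class``, ``owl:sameAs`` declares
    ``owl:NamedIndividual``, property predicates declare
    ``owl:ObjectProperty``. SKOS match predicates default to class entities
    (*skos_entity_kind* overrides). An entity used under predicates of two
    different kinds raises :class:`KindConflict`.
    """
    pm = _entity_pm(ms)
    kinds: Dict[str, str] = {}
    for m in ms.mappings:
        descriptor = PREDICATES.get(m.predicate_id)
        if descriptor is None:
            kind = "class"  # permissive default for unregistered predicates
        elif descriptor.predicate_id.startswith("skos:"):
            kind = skos_entity_kind
        else:
            kind = descriptor.entity_kind
        for entity in (m.subject_id, m.object_id):
            previous = kinds.setdefault(entity, kind)
            if previous != kind:
                raise KindConflict(entity, {previous, kind})
    declarations = {
        (_expand_entity(entity, pm), RDF.type, _KIND_TO_CLASS[kind])
        for entity, kind in kinds.items()
    }
    return to_rdf_reified(ms) | TripleSet(declarations)
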