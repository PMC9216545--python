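"""Core data model: :class:`Mapping` and :class:`MappingSet`.

A mapping is one directed subject-predicate-object correspondence plus
metadata; a mapping set groups mappings under shared set-level metadata and
a prefix map. Instances are built through :func:`make_mapping`, which
enforces the schema invariants (required slots, CURIE shape, unit-interval
scores, ISO-8601 dates) — or, in lenient mode, preserves offending raw
values so the validator can report them as structured issues instead of
exceptions.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, fields, replace
from typing import Any, Dict, List, Mapping as TMapping, Optional, Tuple, Union

from . import curie as _curie
from .curie import PrefixMap, split_curie
from .errors import (
    CurieError,
    FormatError,
    MissingRequiredSlot,
    RangeError,
    UnknownSlot,
)
from .registry import (
    CARDINALITY_VALUES,
    MAPPING_SET_SLOTS,
    MAPPING_SLOTS,
    MULTIVALUED_SLOTS,
    REQUIRED_MAPPING_SLOTS,
    MatchType,
    PredicateModifier,
    slot_definition,
)

__all__ = ["Mapping", "MappingSet", "make_mapping", "make_mapping_set"]

_Date = _dt.date
Multi = Tuple[str, ...]


@dataclass(frozen=True)
class Mapping:
    """One mapping row: the 38 mapping-level slots.

    Absent single-valued slots are ``None``; absent multivalued slots are
    empty tuples. In lenient construction a field may hold an un-coerced raw
    string (e.g. an out-of-range confidence); the validator reports these.
    """

    subject_id: Optional[str] = None
    subject_label: Optional[str] = None
    subject_category: Optional[str] = None
    predicate_id: Optional[str] = None
    predicate_label: Optional[str] = None
    predicate_modifier: Optional[Union[PredicateModifier, str]] = None
    object_id: Optional[str] = None
    object_label: Optional[str] = None
    object_category: Optional[str] = None
    match_type: Optional[Union[MatchType, str]] = None
    mapping_cardinality: Optional[str] = None
    author_id: Multi = ()
    author_label: Optional[str] = None
    reviewer_id: Multi = ()
    reviewer_label: Optional[str] = None
    creator_id: Multi = ()
    creator_label: Optional[str] = None
    license: Optional[str] = None
    subject_source: Optional[str] = None
    subject_source_version: Optional[str] = None
    object_source: Optional[str] = None
    object_source_version: Optional[str] = None
    mapping_provider: Optional[str] = None
    mapping_tool: Optional[str] = None
    mapping_tool_version: Optional[str] = None
    mapping_date: Optional[Union[_Date, str]] = None
    publication_date: Optional[Union[_Date, str]] = None
    confidence: Optional[Union[float, str]] = None
    subject_match_field: Multi = ()
    object_match_field: Multi = ()
    match_string: Multi = ()
    subject_preprocessing: Multi = ()
    object_preprocessing: Multi = ()
    semantic_similarity_score: Optional[Union[float, str]] = None
    semantic_similarity_measure: Optional[str] = None
    see_also: Multi = ()
    other: Optional[str] = None
    comment: Optional[str] = None

    def get(self, slot: str) -> Any:
        return getattr(self, slot)

    def populated_slots(self) -> List[str]:
        """Names of slots carrying a value, in registry order."""
        out = []
        for d in MAPPING_SLOTS:
            v = getattr(self, d.name)
            if v is not None and v != ():
                out.append(d.name)
        return out

    def is_negated(self) -> bool:
        return self.predicate_modifier == PredicateModifier.Not

    def evolve(self, **changes: Any) -> "Mapping":
        return replace(self, **changes)


@dataclass
class MappingSet:
    """A mapping set: the 23 set-level slots plus an ordered mapping list."""

    mapping_set_id: str = ""
    mapping_set_version: Optional[str] = None
    mapping_set_description: Optional[str] = None
    curie_map: PrefixMap = field(default_factory=PrefixMap)
    creator_id: Multi = ()
    creator_label: Optional[str] = None
    license: Optional[str] = None
    subject_source: Optional[str] = None
    subject_source_version: Optional[str] = None
    object_source: Optional[str] = None
    object_source_version: Optional[str] = None
    mapping_provider: Optional[str] = None
    mapping_tool: Optional[str] = None
    mapping_tool_version: Optional[str] = None
    mapping_date: Optional[Union[_Date, str]] = None
    publication_date: Optional[Union[_Date, str]] = None
    subject_match_field: Multi = ()
    object_match_field: Multi = ()
    subject_preprocessing: Multi = ()
    object_preprocessing: Multi = ()
    see_also: Multi = ()
    other: Optional[str] = None
    comment: Optional[str] = None
    mappings: List[Mapping] = field(default_factory=list)

    def populated_set_slots(self) -> List[str]:
        out = []
        for d in MAPPING_SET_SLOTS:
            v = getattr(self, d.name)
            if d.name == "curie_map":
                if len(self.curie_map):
                    out.append(d.name)
            elif v is not None and v != () and v != "":
                out.append(d.name)
        return out

    def with_mappings(self, mappings: List[Mapping]) -> "MappingSet":
        clone = MappingSet(**{f.name: getattr(self, f.name) for f in fields(self) if f.name != "mappings"})
        clone.mappings = list(mappings)
        return clone


# --------------------------------------------------------------------------
# construction / coercion


def _coerce_date(value: Any) -> _Date:
    if isinstance(value, _Date) and not isinstance(value, _dt.datetime):
        return value
    if isinstance(value, _dt.datetime):
        return value.date()
    if isinstance(value, str):
        try:
            return _dt.date.fromisoformat(value)
        except ValueError:
            pass
        # Version-string style dates like "1 January 2020" are normalized
        # when unambiguous.
        for fmt in ("%d %B %Y", "%B %d, %Y"):
            try:
                return _dt.datetime.strptime(value, fmt).date()
            except ValueError:
                continue
    raise FormatError(f"not an ISO-8601 (YYYY-MM-DD) date: {value!r}")


def _coerce_score(slot: str, value: Any) -> float:
    try:
        score = float(value)
    except (TypeError, ValueError):
        raise FormatError(f"{slot} is not a number: {value!r}") from None
    if not 0.0 <= score <= 1.0:
        raise RangeError(f"{slot} outside [0,1]: {score}")
    return score


def _coerce_multi(value: Any) -> Multi:
    if value is None or value == "":
        return ()
    if isinstance(value, str):
        return (value,)
    return tuple(str(v) for v in value)


def _coerce(slot: str, value: Any):
    d = slot_definition(slot)
    if d.multivalued:
        return _coerce_multi(value)
    if value is None or value == "":
        return None
    if d.datatype == "match_type":
        if isinstance(value, MatchType):
            return value
        try:
            return MatchType(value)
        except ValueError:
            raise FormatError(f"unknown match_type: {value!r}") from None
    if d.datatype == "predicate_modifier":
        if isinstance(value, PredicateModifier):
            return value
        try:
            return PredicateModifier(value)
        except ValueError:
            raise FormatError(f"unknown predicate_modifier: {value!r}") from None
    if d.datatype == "date":
        return _coerce_date(value)
    if d.datatype == "double":
        return _coerce_score(slot, value)
    if d.datatype == "entity_reference":
        split_curie(value)  # shape check; resolution is the caller's concern
        return value
    if slot == "mapping_cardinality":
        if value not in CARDINALITY_VALUES:
            raise FormatError(f"mapping_cardinality must be one of {CARDINALITY_VALUES}: {value!r}")
        return value
    return str(value)


_MAPPING_FIELD_NAMES = frozenset(d.name for d in MAPPING_SLOTS)


def make_mapping(record: TMapping[str, Any], *, strict: bool = True) -> Mapping:
    """Build a :class:`Mapping` from a slot-name -> value table.

    Strict mode raises :class:`MissingRequiredSlot`, :class:`RangeError`,
    :class:`FormatError` or :class:`UnknownSlot` on invalid input. Lenient
    mode keeps un-coercible values as raw strings (the validator reports
    them) and silently folds unknown keys into ``other``.
    """
    values: Dict[str, Any] = {}
    extras: List[str] = []
    for key, value in record.items():
        if key not in _MAPPING_FIELD_NAMES:
            if strict:
                raise UnknownSlot(f"unknown mapping slot: {key!r}")
            if value not in (None, ""):
                extras.append(f"{key}={value}")
            continue
        try:
            values[key] = _coerce(key, value)
        except (FormatError, RangeError, CurieError):
            if strict:
                raise
            values[key] = _coerce_multi(value) if key in MULTIVALUED_SLOTS else str(value)
    for name in REQUIRED_MAPPING_SLOTS:
        if values.get(name) in (None, "", ()):
            if strict:
                raise MissingRequiredSlot(name)
            values[name] = None
    if extras:
        other = values.get("other")
        joined = "; ".join(extras)
        values["other"] = f"{other}; {joined}" if other else joined
    return Mapping(**values)


_SET_FIELD_NAMES = frozenset(d.name for d in MAPPING_SET_SLOTS)


def make_mapping_set(
    metadata: TMapping[str, Any],
    mappings: Optional[List[Mapping]] = None,
    *,
    strict: bool = True,
) -> MappingSet:
    """Build a :class:`MappingSet` from a set-slot -> value table."""
    values: Dict[str, Any] = {}
    extras: List[str] = []
    for key, value in metadata.items():
        if key not in _SET_FIELD_NAMES:
            if strict:
                raise UnknownSlot(f"unknown mapping-set slot: {key!r}")
            if value not in (None, ""):
                extras.append(f"{key}={value}")
            continue
        if key == "curie_map":
            values[key] = value if isinstance(value, PrefixMap) else PrefixMap(value or {})
            continue
        try:
            values[key] = _coerce(key, value)
        except (FormatError, RangeError, CurieError):
            if strict:
                raise
            values[key] = _coerce_multi(value) if key in MULTIVALUED_SLOTS else str(value)
    if extras:
        other = values.get("other")
        joined = "; ".join(extras)
        values["other"] = f"{other}; {joined}" if other else joined
    if values.get("mapping_set_id") is None:
        values["mapping_set_id"] = ""
    ms = MappingSet(**values)
    ms.mappings = list(mappings or [])
    return ms


def resolvable(reference: str, pm: PrefixMap) -> bool:
    """True when *reference* is a CURIE whose prefix is declared or builtin."""
    if not _curie.is_curie(reference):
        return False
    prefix, _ = split_curie(reference)
    return pm.declares(prefix)
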