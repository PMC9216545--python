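"""Merging, deduplication, cardinality and reconciliation of mapping sets.

Two ideas from mapping-harmonization practice shape this module. First,
"one row per mapping rule": the same subject/predicate/object triple may
legitimately appear on several rows that differ in how the match was found
(label vs synonym, lexical vs logical); :func:`dedup` therefore only
collapses rows identical on *all* populated slots, while
:func:`collapse_rules` is the deliberate inverse that folds rule rows into
one consolidated mapping. Second, explicit rejection: when a uniqueness
policy discards a candidate mapping (the Mondo-style "no external term maps
to more than one internal term" rule), the loser is not silently dropped
but re-emitted as a negated mapping, so consumers can distinguish "rejected"
from "never considered".
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .curie import merge_prefix_maps
from .errors import SssomError
from .model import Mapping, MappingSet
from .registry import MatchType, PredicateModifier, Strength, predicate_class

__all__ = [
    "ConflictKind",
    "ConflictReport",
    "merge",
    "dedup",
    "collapse_rules",
    "compute_cardinality",
    "reconcile_unique_object",
    "detect_conflicts",
]


def merge(sets: Sequence[MappingSet], new_id: str) -> MappingSet:
    """Concatenate mapping sets under a fresh id.

    Mappings keep input order; prefix maps are unioned (clashes raise);
    source set ids are recorded in ``see_also``.
    """
    if not sets:
        raise SssomError("merge requires at least one mapping set")
    pm = sets[0].curie_map
    for other in sets[1:]:
        pm = merge_prefix_maps(pm, other.curie_map)
    merged = MappingSet(mapping_set_id=new_id, curie_map=pm)
    see_also: List[str] = []
    for s in sets:
        if s.mapping_set_id and s.mapping_set_id not in see_also:
            see_also.append(s.mapping_set_id)
        merged.mappings.extend(s.mappings)
    merged.see_also = tuple(see_also)
    # shared provenance that is unanimous can be kept; anything else is
    # per-source and dropped from the set level
    licenses = {s.license for s in sets if s.license}
    if len(licenses) == 1:
        merged.license = licenses.pop()
    return merged


def dedup(ms: MappingSet) -> MappingSet:
    """Collapse rows identical on all populated slots; first wins, order kept."""
    seen = set()
    out: List[Mapping] = []
    for m in ms.mappings:
        if m in seen:
            continue
        seen.add(m)
        out.append(m)
    return ms.with_mappings(out)


_RuleKey = Tuple[Optional[str], Optional[str], object, Optional[str]]


def _rule_key(m: Mapping) -> _RuleKey:
    return (m.subject_id, m.predicate_id, m.predicate_modifier, m.object_id)


def _union(*tuples: Tuple[str, ...]) -> Tuple[str, ...]:
    out: List[str] = []
    for tup in tuples:
        for v in tup:
            if v not in out:
                out.append(v)
    return tuple(out)


def collapse_rules(ms: MappingSet) -> MappingSet:
    """Fold rows sharing (subject, predicate, modifier, object) into one.

    Confidence becomes the maximum over rules; match_type is kept when
    unanimous and degrades to Complex otherwise; match fields, match
    strings and preprocessing steps are unioned in first-seen order. All
    other metadata is taken from the first rule row.
    """
    groups: Dict[_RuleKey, List[Mapping]] = {}
    order: List[_RuleKey] = []
    for m in ms.mappings:
        key = _rule_key(m)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(m)

    out: List[Mapping] = []
    for key in order:
        rows = groups[key]
        if len(rows) == 1:
            out.append(rows[0])
            continue
        first = rows[0]
        confidences = [r.confidence for r in rows if isinstance(r.confidence, float)]
        match_types = {r.match_type for r in rows}
        out.append(
            first.evolve(
                confidence=max(confidences) if confidences else first.confidence,
                match_type=match_types.pop() if len(match_types) == 1 else MatchType.Complex,
                subject_match_field=_union(*(r.subject_match_field for r in rows)),
                object_match_field=_union(*(r.object_match_field for r in rows)),
                match_string=_union(*(r.match_string for r in rows)),
                subject_preprocessing=_union(*(r.subject_preprocessing for r in rows)),
                object_preprocessing=_union(*(r.object_preprocessing for r in rows)),
            )
        )
    return ms.with_mappings(out)


def compute_cardinality(ms: MappingSet) -> MappingSet:
    """Annotate every non-negated row with 1:1 / 1:n / n:1 / n:n.

    For a row (s, o): ``1:n`` when s maps to several distinct objects,
    ``n:1`` when several subjects map to o, ``n:n`` when both. Negated rows
    neither receive a cardinality nor count toward one.
    """
    objects_of: Dict[str, set] = defaultdict(set)
    subjects_of: Dict[str, set] = defaultdict(set)
    for m in ms.mappings:
        if m.is_negated() or not m.subject_id or not m.object_id:
            continue
        objects_of[m.subject_id].add(m.object_id)
        subjects_of[m.object_id].add(m.subject_id)

    out: List[Mapping] = []
    for m in ms.mappings:
        if m.is_negated() or not m.subject_id or not m.object_id:
            out.append(m)
            continue
        many_objects = len(objects_of[m.subject_id]) > 1
        many_subjects = len(subjects_of[m.object_id]) > 1
        label = f"{'n' if many_subjects else '1'}:{'n' if many_objects else '1'}"
        out.append(m.evolve(mapping_cardinality=label))
    return ms.with_mappings(out)


_MATCH_TYPE_RANK = {
    MatchType.HumanCurated: 4,
    MatchType.Logical: 3,
    MatchType.Lexical: 2,
    MatchType.SemanticSimilarity: 1,
    MatchType.Complex: 0,
}


def _winner_key(m: Mapping) -> Tuple[float, int, str]:
    """Sort key: best candidate first (min)."""
    confidence = m.confidence if isinstance(m.confidence, float) else -1.0
    rank = _MATCH_TYPE_RANK.get(m.match_type, -1)
    return (-confidence, -rank, m.subject_id or "")


def reconcile_unique_object(ms: MappingSet) -> Tuple[MappingSet, MappingSet]:
    """Enforce at most one accepted EXACT mapping per object term.

    Among non-negated EXACT-class rows sharing an object_id, the winner is
    picked by higher confidence, then match-type trust rank (HumanCurated >
    Logical > Lexical > SemanticSimilarity > Complex), then the
    lexicographically smallest subject_id. Losers are re-emitted in the
    rejected set with ``predicate_modifier = Not`` and a comment recording
    why. Rows outside the EXACT class (and already-negated rows) pass
    through accepted untouched.
    """
    exact_by_object: Dict[str, List[int]] = defaultdict(list)
    for i, m in enumerate(ms.mappings):
        if m.is_negated() or not m.object_id or not m.predicate_id:
            continue
        if predicate_class(m.predicate_id) is Strength.EXACT:
            exact_by_object[m.object_id].append(i)

    rejected_idx: Dict[int, str] = {}
    for object_id, indices in exact_by_object.items():
        if len(indices) < 2:
            continue
        winner = min(indices, key=lambda i: (_winner_key(ms.mappings[i]), i))
        for i in indices:
            if i != winner:
                rejected_idx[i] = (
                    f"rejected by unique-object reconciliation: {object_id} already "
                    f"mapped from {ms.mappings[winner].subject_id}"
                )

    accepted_rows: List[Mapping] = []
    rejected_rows: List[Mapping] = []
    for i, m in enumerate(ms.mappings):
        if i in rejected_idx:
            reason = rejected_idx[i]
            comment = f"{m.comment}; {reason}" if m.comment else reason
            rejected_rows.append(
                m.evolve(predicate_modifier=PredicateModifier.Not, comment=comment)
            )
        else:
            accepted_rows.append(m)

    accepted = ms.with_mappings(accepted_rows)
    rejected = ms.with_mappings(rejected_rows)
    if ms.mapping_set_id:
        accepted.mapping_set_id = ms.mapping_set_id + "#accepted"
        rejected.mapping_set_id = ms.mapping_set_id + "#rejected"
    return accepted, rejected


class ConflictKind(enum.Enum):
    NEGATION_CLASH = "NEGATION_CLASH"
    STRENGTH_CLASH = "STRENGTH_CLASH"


@dataclass(frozen=True)
class ConflictReport:
    kind: ConflictKind
    pair: Tuple[str, str]  # (subject_id, object_id)
    rows: Tuple[int, ...]


def detect_conflicts(ms: MappingSet) -> List[ConflictReport]:
    """Find pairs asserted and rejected at once, or under clashing strengths.

    NEGATION_CLASH: the same (subject, object) pair with the same predicate
    strength class appears both negated and non-negated. STRENGTH_CLASH:
    the pair appears under EXACT and also under RELATED, BROAD or NARROW.
    Reports are sorted by pair.
    """
    by_pair: Dict[Tuple[str, str], List[int]] = defaultdict(list)
    for i, m in enumerate(ms.mappings):
        if m.subject_id and m.object_id and m.predicate_id:
            by_pair[(m.subject_id, m.object_id)].append(i)

    reports: List[ConflictReport] = []
    for pair in sorted(by_pair):
        indices = by_pair[pair]
        by_class: Dict[Strength, List[int]] = defaultdict(list)
        for i in indices:
            by_class[predicate_class(ms.mappings[i].predicate_id)].append(i)
        for strength, members in sorted(by_class.items(), key=lambda kv: kv[0].value):
            negated = [i for i in members if ms.mappings[i].is_negated()]
            positive = [i for i in members if not ms.mappings[i].is_negated()]
            if negated and positive:
                reports.append(
                    ConflictReport(ConflictKind.NEGATION_CLASH, pair, tuple(sorted(members)))
                )
        positives_by_class = {
            strength
            for strength, members in by_class.items()
            if any(not ms.mappings[i].is_negated() for i in members)
        }
        weaker = {Strength.RELATED, Strength.BROAD, Strength.NARROW}
        if Strength.EXACT in positives_by_class and positives_by_class & weaker:
            involved = [
                i
                for i in indices
                if not ms.mappings[i].is_negated()
                and predicate_class(ms.mappings[i].predicate_id) in (weaker | {Strength.EXACT})
            ]
            reports.append(ConflictReport(ConflictKind.STRENGTH_CLASH, pair, tuple(involved)))
    return reports
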