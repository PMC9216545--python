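"""Rule-based mapping-set validator.

Thirteen rules (R01-R13) cover required slots, identifier hygiene,
controlled vocabularies, score ranges, date formats and a handful of lint
checks that encode known interpretation hazards — notably R12, which flags
preprocessing metadata without the match fields it modifies (ignoring
preprocessing when reading match fields can silently change what a match
means). Issues are data, not exceptions: validation never raises on bad
content, it reports.
"""

from __future__ import annotations

import datetime as _dt
import enum
from dataclasses import dataclass
from typing import Dict, List, Tuple, Union

from .curie import is_curie, split_curie
from .model import Mapping, MappingSet
from .registry import (
    ENTITY_REFERENCE_SLOTS,
    MAPPING_SLOTS,
    REQUIRED_MAPPING_SLOTS,
    MatchType,
    PredicateModifier,
    Strength,
    predicate_class,
)

__all__ = ["Severity", "ValidationIssue", "RULES", "validate"]


class Severity(enum.Enum):
    ERROR = "ERROR"
    WARNING = "WARNING"
    INFO = "INFO"


#: code -> (severity, short description)
RULES: Dict[str, Tuple[Severity, str]] = {
    "R01": (Severity.ERROR, "required mapping slots present"),
    "R02": (Severity.ERROR, "mapping_set_id present"),
    "R03": (Severity.WARNING, "license present"),
    "R04": (Severity.ERROR, "CURIEs well-formed and prefixes resolvable"),
    "R05": (Severity.ERROR, "match_type drawn from the five-value vocabulary"),
    "R06": (Severity.INFO, "predicate outside the recommended table"),
    "R07": (Severity.ERROR, "confidence/semantic_similarity_score in [0,1]"),
    "R08": (Severity.WARNING, "SemanticSimilarity rows carry a measure"),
    "R09": (Severity.WARNING, "Lexical rows carry match fields"),
    "R10": (Severity.ERROR, "dates are ISO-8601 (YYYY-MM-DD)"),
    "R11": (Severity.ERROR, "predicate_modifier value is 'Not'"),
    "R12": (Severity.WARNING, "preprocessing without match_field (idempotency hazard)"),
    "R13": (Severity.INFO, "duplicate identical rows"),
}

Locus = Union[int, str]


@dataclass(frozen=True)
class ValidationIssue:
    code: str
    severity: Severity
    locus: Locus  # row index (0-based) or "set"
    message: str


def _issue(code: str, locus: Locus, message: str) -> ValidationIssue:
    return ValidationIssue(code, RULES[code][0], locus, message)


def _er_values(m: Mapping, slot: str):
    v = getattr(m, slot, None)
    if isinstance(v, tuple):
        return v
    return (v,) if v else ()


_ER_MAPPING_SLOTS = tuple(
    d.name for d in MAPPING_SLOTS if d.name in ENTITY_REFERENCE_SLOTS
)
_DATE_SLOTS = ("mapping_date", "publication_date")
_SCORE_SLOTS = ("confidence", "semantic_similarity_score")


def validate(ms: MappingSet) -> List[ValidationIssue]:
    """Apply the full rule table; issues sorted by (code, locus)."""
    issues: List[ValidationIssue] = []

    # set level
    if not ms.mapping_set_id:
        issues.append(_issue("R02", "set", "mapping_set_id is missing"))
    if not ms.license:
        issues.append(_issue("R03", "set", "license is missing"))

    seen_rows: Dict[Mapping, int] = {}
    for i, m in enumerate(ms.mappings):
        for name in REQUIRED_MAPPING_SLOTS:
            if getattr(m, name) in (None, "", ()):
                issues.append(_issue("R01", i, f"required slot {name} is missing"))

        for slot in _ER_MAPPING_SLOTS:
            for value in _er_values(m, slot):
                if not is_curie(value):
                    issues.append(_issue("R04", i, f"{slot} is not a CURIE: {value!r}"))
                elif not ms.curie_map.declares(split_curie(value)[0]):
                    issues.append(
                        _issue("R04", i, f"prefix {split_curie(value)[0]!r} of {slot} not resolvable")
                    )

        mt = m.match_type
        if mt is not None and not isinstance(mt, MatchType):
            issues.append(_issue("R05", i, f"unknown match_type: {mt!r}"))

        pid = m.predicate_id
        if pid and is_curie(pid) and predicate_class(pid) is Strength.UNKNOWN:
            issues.append(_issue("R06", i, f"unrecommended predicate: {pid}"))

        for slot in _SCORE_SLOTS:
            v = getattr(m, slot)
            if v is None:
                continue
            try:
                score = float(v)
            except (TypeError, ValueError):
                issues.append(_issue("R07", i, f"{slot} is not a number: {v!r}"))
                continue
            if not 0.0 <= score <= 1.0:
                issues.append(_issue("R07", i, f"{slot} outside [0,1]: {score}"))

        if mt is MatchType.SemanticSimilarity and not m.semantic_similarity_measure:
            issues.append(_issue("R08", i, "SemanticSimilarity row lacks semantic_similarity_measure"))
        if mt is MatchType.Lexical and (not m.subject_match_field or not m.object_match_field):
            issues.append(_issue("R09", i, "Lexical row lacks subject/object match_field"))

        for slot in _DATE_SLOTS:
            v = getattr(m, slot)
            if v is not None and not isinstance(v, _dt.date):
                issues.append(_issue("R10", i, f"{slot} is not an ISO-8601 date: {v!r}"))

        pm = m.predicate_modifier
        if pm is not None and not isinstance(pm, PredicateModifier):
            issues.append(_issue("R11", i, f"invalid predicate_modifier: {pm!r}"))

        if m.subject_preprocessing and not m.subject_match_field:
            issues.append(_issue("R12", i, "subject_preprocessing set but subject_match_field absent"))
        if m.object_preprocessing and not m.object_match_field:
            issues.append(_issue("R12", i, "object_preprocessing set but object_match_field absent"))

        try:
            first = seen_rows.setdefault(m, i)
        except TypeError:  # unhashable raw values cannot be duplicates of typed rows
            first = i
        if first != i:
            issues.append(_issue("R13", i, f"identical to row {first}"))

    issues.sort(key=lambda it: (it.code, -1 if it.locus == "set" else it.locus))
    return issues
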