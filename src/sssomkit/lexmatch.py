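"""Lexical matcher over flat label tables, emitting one row per mapping rule.

The matcher consumes two tables of (entity_id, field, text) records — the
field says *which* naming property carried the text: the primary label
(rdfs:label), an exact synonym (oboInOwl:hasExactSynonym) or a shared match
term (skos:exactMatch) — and pairs up records whose preprocessed texts are
equal. Each agreeing field pair yields its own output row ("one row per
mapping rule"), so a pair of terms matching on both labels and synonyms
produces two rows for the same subject/predicate/object.

Every row carries full match metadata: the match fields, the shared match
string, the preprocessing steps applied, and a confidence from the rule
weights. Destructive preprocessing (stripping punctuation or digits) is
both supported and penalized: "Alzheimer 2" and "Alzheimer 3" are different
concepts, and only digit-stripping makes them (misleadingly) equal — the
populated preprocessing slots are what lets a consumer notice.
"""

from __future__ import annotations

import re
import unicodedata
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping as TMapping, Optional, Sequence, Tuple, Union

from .curie import PrefixMap, split_curie
from .errors import FormatError, SssomError
from .model import Mapping, MappingSet, make_mapping
from .registry import MatchType

__all__ = [
    "MATCH_FIELDS",
    "PREPROCESSING_STEPS",
    "LabelRecord",
    "MatchConfig",
    "preprocess",
    "match",
    "read_label_table",
    "write_label_table",
]

MATCH_FIELDS = ("rdfs:label", "oboInOwl:hasExactSynonym", "skos:exactMatch")

_WS_RE = re.compile(r"\s+")


def _lowercase(text: str) -> str:
    return text.casefold()


def _strip_nonalphanumeric(text: str) -> str:
    # letters and digits survive; spaces survive so word boundaries remain
    return "".join(ch for ch in text if ch.isalnum() or ch == " ")


def _strip_digits(text: str) -> str:
    return "".join(ch for ch in text if not ch.isdigit())


def _collapse_whitespace(text: str) -> str:
    return _WS_RE.sub(" ", text).strip()


PREPROCESSING_STEPS = {
    "lowercase": _lowercase,
    "strip_nonalphanumeric": _strip_nonalphanumeric,
    "strip_digits": _strip_digits,
    "collapse_whitespace": _collapse_whitespace,
}

#: steps that can merge distinct concepts; they cost confidence
_DESTRUCTIVE = frozenset({"strip_nonalphanumeric", "strip_digits"})


def preprocess(text: str, steps: Sequence[str]) -> str:
    """Apply preprocessing steps left to right."""
    for step in steps:
        if step not in PREPROCESSING_STEPS:
            raise SssomError(f"unknown preprocessing step: {step!r}")
        text = PREPROCESSING_STEPS[step](text)
    return text


@dataclass(frozen=True)
class LabelRecord:
    """One naming assertion: entity, the property that names it, the text."""

    entity_id: str
    field: str
    text: str

    def __post_init__(self):
        split_curie(self.entity_id)
        if self.field not in MATCH_FIELDS:
            raise FormatError(f"field must be one of {MATCH_FIELDS}: {self.field!r}")
        if not self.text:
            raise FormatError("label text must be non-empty")


_FIELD_CLASS = {
    "rdfs:label": "label",
    "oboInOwl:hasExactSynonym": "synonym",
    "skos:exactMatch": "synonym",
}

_BASE_WEIGHTS: Dict[FrozenSet[str], float] = {
    frozenset({"label"}): 0.9,
    frozenset({"label", "synonym"}): 0.8,
    frozenset({"synonym"}): 0.7,
}


@dataclass(frozen=True)
class MatchConfig:
    """Matcher settings: preprocessing pipeline, rule weights, predicate."""

    preprocessing: Tuple[str, ...] = ("lowercase", "collapse_whitespace")
    weights: Optional[TMapping[FrozenSet[str], float]] = None
    predicate: str = "skos:exactMatch"

    def rule_confidence(self, subject_field: str, object_field: str) -> float:
        key = frozenset({_FIELD_CLASS[subject_field], _FIELD_CLASS[object_field]})
        table = self.weights if self.weights is not None else _BASE_WEIGHTS
        base = table[key]
        penalty = 0.05 * sum(1 for s in self.preprocessing if s in _DESTRUCTIVE)
        return max(0.0, round(base - penalty, 6))


def match(
    subjects: Sequence[LabelRecord],
    objects: Sequence[LabelRecord],
    config: MatchConfig = MatchConfig(),
    *,
    prefix_map: Optional[PrefixMap] = None,
    mapping_set_id: str = "https://example.org/sssom-kit/lexmatch",
) -> MappingSet:
    """Pair subject and object records with equal preprocessed texts.

    Emits one Lexical mapping per agreeing (subject record, object record)
    pair — one row per mapping rule — sorted by (subject_id, object_id,
    confidence descending). Self-matches (identical entity on both sides)
    are suppressed; entity ids appearing in both tables trigger a warning
    but rows are still produced.
    """
    overlap = {r.entity_id for r in subjects} & {r.entity_id for r in objects}
    if overlap:
        warnings.warn(
            f"{len(overlap)} entity id(s) appear in both tables, e.g. {sorted(overlap)[0]}",
            stacklevel=2,
        )

    index: Dict[str, List[LabelRecord]] = {}
    for rec in objects:
        key = preprocess(rec.text, config.preprocessing)
        if key:
            index.setdefault(key, []).append(rec)

    steps = tuple(config.preprocessing)
    rows: List[Mapping] = []
    for srec in subjects:
        key = preprocess(srec.text, config.preprocessing)
        if not key:
            continue
        for orec in index.get(key, ()):
            if orec.entity_id == srec.entity_id:
                continue
            rows.append(
                make_mapping(
                    {
                        "subject_id": srec.entity_id,
                        "predicate_id": config.predicate,
                        "object_id": orec.entity_id,
                        "match_type": MatchType.Lexical,
                        "subject_match_field": (srec.field,),
                        "object_match_field": (orec.field,),
                        "match_string": (key,),
                        "subject_preprocessing": steps,
                        "object_preprocessing": steps,
                        "confidence": config.rule_confidence(srec.field, orec.field),
                        "mapping_tool": "sssom-kit-lexmatch",
                    }
                )
            )

    rows.sort(
        key=lambda m: (
            m.subject_id,
            m.object_id,
            -(m.confidence or 0.0),
            m.subject_match_field,
            m.object_match_field,
        )
    )
    ms = MappingSet(
        mapping_set_id=mapping_set_id,
        mapping_tool="sssom-kit-lexmatch",
        curie_map=prefix_map or PrefixMap(),
        mappings=rows,
    )
    return ms


# --------------------------------------------------------------------------
# label-table I/O (3-column TSV: entity_id, field, text)

_LABEL_COLUMNS = ("entity_id", "field", "text")


def read_label_table(path: Union[str, Path]) -> List[LabelRecord]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    rows = [l for l in lines if l.strip()]
    if not rows or tuple(rows[0].split("\t")) != _LABEL_COLUMNS:
        raise FormatError(f"label table must start with header {'/'.join(_LABEL_COLUMNS)}")
    records = []
    for line in rows[1:]:
        cells = line.split("\t")
        if len(cells) != 3:
            raise FormatError(f"label table row needs 3 cells: {line!r}")
        records.append(LabelRecord(*cells))
    return records


def write_label_table(records: Sequence[LabelRecord], path: Union[str, Path]) -> None:
    lines = ["\t".join(_LABEL_COLUMNS)]
    lines += [f"{r.entity_id}\t{r.field}\t{r.text}" for r in records]
    Path(path).write_text("".join(l + "\n" for l in lines), encoding="utf-8")
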