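"""Reader/writer for the SSSOM TSV format.

A mapping-set file has two parts: a metadata header of commented YAML
(every line prefixed with ``#``) holding the set-level slots including the
curie_map, and a tab-separated table whose first row names mapping-level
slots. The header can be *embedded* in the same file or supplied as an
*external* plain-YAML file next to a bare table.

The format deliberately has no quoting dialect: tabs, newlines and cell
values starting with ``#`` are illegal, which keeps files consumable by
generic table tooling. Multivalued cells use ``|`` as delimiter. Writing is
canonical — header keys sorted alphabetically, columns in registry
declaration order — so identical sets produce identical bytes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Dict, List, Optional, Tuple, Union

import yaml

from .curie import PrefixMap, split_curie
from .errors import (
    CurieError,
    HeaderError,
    MissingRequiredColumn,
    RaggedRow,
    SerializationError,
    UndeclaredPrefix,
    UnknownColumn,
)
from .model import Mapping, MappingSet, make_mapping, make_mapping_set
from .registry import (
    ENTITY_REFERENCE_SLOTS,
    MAPPING_SET_SLOTS,
    MAPPING_SLOTS,
    MULTIVALUED_SLOTS,
    REQUIRED_MAPPING_SLOTS,
    MatchType,
    PredicateModifier,
)

__all__ = [
    "MappingSetDocument",
    "parse",
    "parse_document",
    "write",
    "externalize",
    "embed",
    "read_tsv",
    "write_tsv",
]

_MAPPING_SLOT_NAMES = tuple(d.name for d in MAPPING_SLOTS)
_FORBIDDEN = ("\t", "\n", "\r")


@dataclass
class MappingSetDocument:
    """A serialized mapping set: header text, table text and mode.

    In embedded mode ``header_text`` is the commented YAML block (every line
    starts with ``#``); in external mode it is plain YAML destined for a
    separate file.
    """

    header_text: str
    table_text: str
    mode: str = "embedded"  # "embedded" | "external"

    @property
    def text(self) -> str:
        """Single-file rendering (embedded mode only)."""
        if self.mode != "embedded":
            raise SerializationError("external documents are two files; use header_text/table_text")
        return self.header_text + self.table_text


# --------------------------------------------------------------------------
# parsing


def _split_embedded(text: str) -> Tuple[List[str], List[str]]:
    header_lines: List[str] = []
    table_lines: List[str] = []
    in_header = True
    for line in text.splitlines():
        if in_header and line.startswith("#"):
            header_lines.append(line)
        else:
            in_header = False
            table_lines.append(line)
    return header_lines, table_lines


def _strip_comment(line: str) -> str:
    line = line[1:] if line.startswith("#") else line
    return line[1:] if line.startswith(" ") else line


def _parse_header(yaml_text: str, strict: bool) -> Dict[str, Any]:
    try:
        data = yaml.safe_load(yaml_text)
    except yaml.YAMLError as exc:
        raise HeaderError(f"metadata header is not valid YAML: {exc}") from None
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise HeaderError(f"metadata header must be a YAML mapping, got {type(data).__name__}")
    if "curie_map" in data and data["curie_map"] is not None:
        cm = data["curie_map"]
        if not isinstance(cm, dict):
            raise HeaderError("curie_map must be a YAML mapping of prefix to IRI base")
        try:
            data["curie_map"] = PrefixMap(cm)
        except CurieError as exc:
            raise HeaderError(str(exc)) from None
    return data


def _check_prefixes(ms: MappingSet) -> None:
    """Every entity reference in the set must have a resolvable prefix."""

    def check(value: str) -> None:
        prefix, _ = split_curie(value)
        if not ms.curie_map.declares(prefix):
            raise UndeclaredPrefix(prefix)

    for name in ENTITY_REFERENCE_SLOTS & set(d.name for d in MAPPING_SET_SLOTS):
        v = getattr(ms, name, None)
        for item in v if isinstance(v, tuple) else ((v,) if v else ()):
            check(item)
    for m in ms.mappings:
        for name in ENTITY_REFERENCE_SLOTS:
            if not hasattr(m, name):
                continue
            v = getattr(m, name)
            for item in v if isinstance(v, tuple) else ((v,) if v else ()):
                check(item)


def parse_document(document: MappingSetDocument, *, strict: bool = True) -> MappingSet:
    """Parse a :class:`MappingSetDocument` into a :class:`MappingSet`.

    Strict mode raises on unknown columns, missing required columns, ragged
    rows and undeclared prefixes; lenient mode folds unknown columns into
    the ``other`` slot and defers value problems to the validator.
    """
    if document.mode == "embedded":
        header_yaml = "\n".join(_strip_comment(l) for l in document.header_text.splitlines())
    else:
        header_yaml = document.header_text
    metadata = _parse_header(header_yaml, strict)

    table_lines = [l for l in document.table_text.splitlines()]
    # leading '#' lines in the table part of an external-mode pair are not
    # expected, but blank lines anywhere are ignored
    rows = [(i + 1, l) for i, l in enumerate(table_lines) if l.strip() != ""]
    if not rows:
        raise MissingRequiredColumn(REQUIRED_MAPPING_SLOTS[0])
    _, header_row = rows[0]
    columns = header_row.split("\t")
    if strict:
        for col in columns:
            if col not in _MAPPING_SLOT_NAMES:
                raise UnknownColumn(f"unknown column: {col!r}")
    for required in REQUIRED_MAPPING_SLOTS:
        if required not in columns:
            raise MissingRequiredColumn(required)

    mappings: List[Mapping] = []
    for lineno, line in rows[1:]:
        cells = line.split("\t")
        if len(cells) != len(columns):
            raise RaggedRow(lineno)
        record: Dict[str, Any] = {}
        for col, cell in zip(columns, cells):
            if cell == "":
                continue
            record[col] = cell.split("|") if col in MULTIVALUED_SLOTS else cell
        mappings.append(make_mapping(record, strict=strict))

    ms = make_mapping_set(metadata, mappings, strict=strict)
    if strict:
        _check_prefixes(ms)
    return ms


def parse(
    text: str,
    metadata: Optional[str] = None,
    *,
    strict: bool = True,
) -> MappingSet:
    """Parse SSSOM TSV text; pass external-mode YAML metadata via *metadata*."""
    if metadata is not None:
        doc = MappingSetDocument(header_text=metadata, table_text=text, mode="external")
    else:
        header_lines, table_lines = _split_embedded(text)
        doc = MappingSetDocument(
            header_text="".join(l + "\n" for l in header_lines),
            table_text="".join(l + "\n" for l in table_lines),
            mode="embedded",
        )
    return parse_document(doc, strict=strict)


# --------------------------------------------------------------------------
# writing


def _render_scalar(value: Any) -> str:
    if isinstance(value, (MatchType, PredicateModifier)):
        return value.value
    if isinstance(value, float):
        return repr(value)
    if hasattr(value, "isoformat"):
        return value.isoformat()
    return str(value)


def _render_cell(slot: str, value: Any) -> str:
    if value is None or value == ():
        return ""
    if slot in MULTIVALUED_SLOTS:
        items = [_render_scalar(v) for v in value]
        for item in items:
            if "|" in item:
                raise SerializationError(f"'|' inside multivalued {slot} item: {item!r}")
        cell = "|".join(items)
    else:
        cell = _render_scalar(value)
    if any(ch in cell for ch in _FORBIDDEN):
        raise SerializationError(f"tab/newline in {slot} value: {cell!r}")
    if cell.startswith("#"):
        raise SerializationError(f"{slot} value may not start with '#': {cell!r}")
    return cell


def _header_dict(ms: MappingSet) -> Dict[str, Any]:
    out: Dict[str, Any] = {}
    for name in ms.populated_set_slots():
        value = getattr(ms, name)
        if name == "curie_map":
            out[name] = ms.curie_map.as_dict()
        elif isinstance(value, tuple):
            out[name] = list(value)
        elif isinstance(value, float):
            out[name] = value
        else:
            out[name] = value
    return out


def _header_yaml(ms: MappingSet) -> str:
    data = _header_dict(ms)
    if not data:
        return ""
    return yaml.safe_dump(data, sort_keys=True, default_flow_style=False, width=4096, allow_unicode=True)


def _table_text(ms: MappingSet) -> str:
    populated = set(REQUIRED_MAPPING_SLOTS)
    for m in ms.mappings:
        populated.update(m.populated_slots())
    columns = [d.name for d in MAPPING_SLOTS if d.name in populated]
    buf = io.StringIO()
    buf.write("\t".join(columns) + "\n")
    for m in ms.mappings:
        buf.write("\t".join(_render_cell(c, getattr(m, c)) for c in columns) + "\n")
    return buf.getvalue()


def write(ms: MappingSet, mode: str = "embedded") -> MappingSetDocument:
    """Serialize canonically: same set -> identical bytes."""
    header = _header_yaml(ms)
    table = _table_text(ms)
    if mode == "embedded":
        commented = "".join(f"#{line}\n" for line in header.splitlines())
        return MappingSetDocument(header_text=commented, table_text=table, mode="embedded")
    if mode == "external":
        return MappingSetDocument(header_text=header, table_text=table, mode="external")
    raise SerializationError(f"unknown mode: {mode!r}")


def externalize(ms: MappingSet) -> Tuple[str, str]:
    """Split a set into (plain-YAML metadata text, bare TSV table text)."""
    doc = write(ms, mode="external")
    return doc.header_text, doc.table_text


def embed(header: str, table: str) -> MappingSetDocument:
    """Join an external header/table pair into one embedded document."""
    commented = "".join(f"#{line}\n" for line in header.splitlines())
    return MappingSetDocument(header_text=commented, table_text=table, mode="embedded")


# --------------------------------------------------------------------------
# path conveniences


def read_tsv(
    path: Union[str, Path],
    metadata: Optional[Union[str, Path]] = None,
    *,
    strict: bool = True,
) -> MappingSet:
    text = Path(path).read_text(encoding="utf-8")
    meta = Path(metadata).read_text(encoding="utf-8") if metadata is not None else None
    return parse(text, meta, strict=strict)


def write_tsv(ms: MappingSet, path: Union[str, Path], mode: str = "embedded") -> None:
    doc = write(ms, mode=mode)
    if mode == "embedded":
        Path(path).write_text(doc.text, encoding="utf-8")
    else:
        Path(path).write_text(doc.table_text, encoding="utf-8")
        Path(path).with_suffix(Path(path).suffix + ".yml").write_text(
            doc.header_text, encoding="utf-8"
        )
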