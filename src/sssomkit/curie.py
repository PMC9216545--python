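"""Prefix-map management and CURIE <-> IRI conversion.

Identifiers in mapping sets are CURIEs (``prefix:local``). A prefix map binds
each prefix to an absolute IRI base; expansion is plain concatenation and
contraction picks the longest matching base. Five prefixes (owl, rdfs, rdf,
skos, sssom) are builtin so that the recommended mapping predicates always
resolve without any declaration.
"""

from __future__ import annotations

import re
import warnings
from typing import Dict, Iterable, Iterator, Mapping, Optional, Tuple

from .errors import CurieError, NoMatchingPrefix, PrefixClash, UndeclaredPrefix

__all__ = [
    "BUILTIN_PREFIX_MAP",
    "PrefixMap",
    "split_curie",
    "is_curie",
    "expand",
    "contract",
    "merge_prefix_maps",
]

#: Always-resolvable prefixes: the recommended predicates (SKOS/OWL/RDFS) and
#: the native sssom: metadata namespace must parse with an empty prefix map.
BUILTIN_PREFIX_MAP: Dict[str, str] = {
    "owl": "http://www.w3.org/2002/07/owl#",
    "rdfs": "http://www.w3.org/2000/01/rdf-schema#",
    "rdf": "http://www.w3.org/1999/02/22-rdf-syntax-ns#",
    "skos": "http://www.w3.org/2004/02/skos/core#",
    "sssom": "https://w3id.org/sssom/",
}

_PREFIX_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_.]*$")
# Absolute IRI: a scheme followed by a colon (RFC 3987 scheme production).
_IRI_RE = re.compile(r"^[A-Za-z][A-Za-z0-9+.\-]*:\S+$")


def split_curie(curie: str) -> Tuple[str, str]:
    """Split ``prefix:local`` at the *first* colon.

    Local parts may themselves contain colons. Raises :class:`CurieError`
    when the string has no colon, an empty part, or whitespace.
    """
    if not isinstance(curie, str):
        raise CurieError(f"not a string: {curie!r}")
    if any(ch.isspace() for ch in curie):
        raise CurieError(f"CURIE contains whitespace: {curie!r}")
    prefix, sep, local = curie.partition(":")
    if not sep or not prefix or not local:
        raise CurieError(f"not a CURIE (need non-empty prefix:local): {curie!r}")
    return prefix, local


def is_curie(value: str) -> bool:
    try:
        split_curie(value)
    except CurieError:
        return False
    return True


class PrefixMap:
    """An immutable prefix -> IRI-base table.

    Prefixes must match ``[A-Za-z_][A-Za-z0-9_.]*`` and bases must be
    absolute IRIs. Two prefixes sharing one base is suspicious (contraction
    becomes ambiguous) and triggers a warning unless explicitly allowed.
    """

    __slots__ = ("_entries",)

    def __init__(
        self,
        entries: Optional[Mapping[str, str]] = None,
        *,
        allow_duplicate_bases: bool = False,
    ):
        table: Dict[str, str] = {}
        for prefix, base in (entries or {}).items():
            if not _PREFIX_RE.match(prefix):
                raise CurieError(f"invalid prefix: {prefix!r}")
            if not isinstance(base, str) or not _IRI_RE.match(base):
                raise CurieError(f"base for {prefix!r} is not an absolute IRI: {base!r}")
            table[prefix] = base
        if not allow_duplicate_bases:
            seen: Dict[str, str] = {}
            for prefix, base in table.items():
                if base in seen:
                    warnings.warn(
                        f"prefixes {seen[base]!r} and {prefix!r} share base {base!r}",
                        stacklevel=2,
                    )
                seen.setdefault(base, prefix)
        self._entries = dict(sorted(table.items()))

    # -- mapping protocol -------------------------------------------------
    def __getitem__(self, prefix: str) -> str:
        return self._entries[prefix]

    def __contains__(self, prefix: str) -> bool:
        return prefix in self._entries

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, PrefixMap):
            return self._entries == other._entries
        if isinstance(other, dict):
            return self._entries == other
        return NotImplemented

    def __repr__(self) -> str:
        return f"PrefixMap({self._entries!r})"

    def items(self) -> Iterable[Tuple[str, str]]:
        return self._entries.items()

    def as_dict(self) -> Dict[str, str]:
        return dict(self._entries)

    def declares(self, prefix: str) -> bool:
        """True when *prefix* is declared here or builtin."""
        return prefix in self._entries or prefix in BUILTIN_PREFIX_MAP


EMPTY_PREFIX_MAP = PrefixMap()


def _resolved(pm: PrefixMap) -> Dict[str, str]:
    table = dict(BUILTIN_PREFIX_MAP)
    table.update(pm.as_dict())
    return table


def expand(curie: str, pm: PrefixMap = EMPTY_PREFIX_MAP) -> str:
    """Expand a CURIE to an IRI: declared (or builtin) base + local part."""
    prefix, local = split_curie(curie)
    table = _resolved(pm)
    if prefix not in table:
        raise UndeclaredPrefix(prefix)
    return table[prefix] + local


def contract(iri: str, pm: PrefixMap = EMPTY_PREFIX_MAP) -> str:
    """Contract an IRI to a CURIE using the longest matching base.

    Ties between equal-length bases are broken by the lexicographically
    smallest prefix. Raises :class:`NoMatchingPrefix` if nothing matches.
    """
    candidates = [
        (prefix, base)
        for prefix, base in _resolved(pm).items()
        if iri.startswith(base) and len(iri) > len(base)
    ]
    if not candidates:
        raise NoMatchingPrefix(f"no declared base matches {iri!r}")
    prefix, base = min(candidates, key=lambda pb: (-len(pb[1]), pb[0]))
    return f"{prefix}:{iri[len(base):]}"


def merge_prefix_maps(a: PrefixMap, b: PrefixMap) -> PrefixMap:
    """Union two prefix maps; identical duplicates collapse, clashes raise."""
    merged = a.as_dict()
    for prefix, base in b.items():
        if prefix in merged and merged[prefix] != base:
            raise PrefixClash(prefix, merged[prefix], base)
        merged[prefix] = base
    return PrefixMap(merged, allow_duplicate_bases=True)
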