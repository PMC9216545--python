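"""Exception hierarchy for sssomkit.

All library errors derive from :class:`SssomError` so callers (and the CLI)
can distinguish data problems from programming errors.
"""

from __future__ import annotations


class SssomError(Exception):
    """Base class for all sssomkit errors."""


class CurieError(SssomError):
    """A string is not a well-formed CURIE (``prefix:local``)."""


class UndeclaredPrefix(SssomError):
    """A CURIE uses a prefix that is neither declared nor builtin."""

    def __init__(self, prefix: str):
        super().__init__(f"undeclared prefix: {prefix!r}")
        self.prefix = prefix


class NoMatchingPrefix(SssomError):
    """No prefix-map base is a prefix of the IRI being contracted."""


class PrefixClash(SssomError):
    """The same prefix is bound to two different IRI bases."""

    def __init__(self, prefix: str, base_a: str, base_b: str):
        super().__init__(f"prefix {prefix!r} bound to both {base_a!r} and {base_b!r}")
        self.prefix = prefix


class MissingRequiredSlot(SssomError):
    """A required mapping slot is absent or empty."""

    def __init__(self, name: str):
        super().__init__(f"missing required slot: {name}")
        self.name = name


class UnknownSlot(SssomError):
    """A record key is not a registered slot name."""


class RangeError(SssomError):
    """A numeric slot value lies outside its permitted range."""


class FormatError(SssomError):
    """A slot value cannot be coerced to its declared datatype."""


class HeaderError(SssomError):
    """The commented YAML metadata header cannot be parsed."""


class UnknownColumn(SssomError):
    """Strict parsing found a column that is not a mapping-level slot."""


class MissingRequiredColumn(SssomError):
    """The table lacks one of the four required mapping columns."""

    def __init__(self, name: str):
        super().__init__(f"missing required column: {name}")
        self.name = name


class RaggedRow(SssomError):
    """A data row has a different field count than the header row."""

    def __init__(self, line: int):
        super().__init__(f"row at line {line} has wrong field count")
        self.line = line


class SerializationError(SssomError):
    """A value contains characters that the TSV format cannot carry."""


class KindConflict(SssomError):
    """An entity is used both as an OWL individual and as a class/property."""

    def __init__(self, entity: str, kinds):
        super().__init__(f"entity {entity} declared with conflicting kinds: {sorted(kinds)}")
        self.entity = entity
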