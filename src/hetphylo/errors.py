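"""Exception hierarchy shared across the package."""


class HetphyloError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HetphyloError):
    """A file or string does not conform to its declared format."""


class CharacterError(FormatError):
    """A sequence contains a character outside alphabet and missing sets."""

    def __init__(self, taxon: str, column: int, char: str):
        self.taxon = taxon
        self.column = column
        self.char = char
        super().__init__(
            f"illegal character {char!r} for taxon {taxon!r} at column {column}"
        )


class LabelError(FormatError):
    """Duplicate or otherwise invalid taxon labels."""


class UsageError(HetphyloError, ValueError):
    """An operation was called with incompatible or out-of-range arguments."""


class ModelError(HetphyloError):
    """A substitution model violates its structural invariants."""
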