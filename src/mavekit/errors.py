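"""Exception hierarchy.

Variant-syntax errors (raised while parsing variant strings) all derive from
:class:`VariantSyntaxError` and carry the character position at which the
problem was detected, when one is known.  Validation problems found in tables
and collections are *not* exceptions — they are reported as findings (see
:mod:`mavekit.report`); exceptions are reserved for violated preconditions
and unusable inputs.
"""

from __future__ import annotations


class MaveKitError(Exception):
    """Base class for all package errors."""


class VariantSyntaxError(MaveKitError):
    """Base class for variant-string parse errors.

    Parameters
    ----------
    message:
        Human-readable description.
    position:
        0-based character index into the original string at which the
        problem was detected, or None when no single position applies.
    """

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at character {position})"
        super().__init__(message)


class MalformedVariant(VariantSyntaxError):
    """The string violates the variant grammar."""


class UnsupportedFeature(VariantSyntaxError):
    """Valid full-HGVS (or legacy) syntax outside the supported strict subset."""


class OffsetNotAllowed(VariantSyntaxError):
    """An intronic/offset position was used outside splice-context parsing."""


class InvalidVariant(MaveKitError):
    """A programmatically built variant violates its invariants."""


class MalformedUrn(MaveKitError):
    """The string is not a valid MaveDB-style URN."""


class InvalidUrn(MaveKitError):
    """A programmatically built URN violates its invariants."""


class BadAlphabet(MaveKitError):
    """Sequence contains characters outside the expected alphabet."""


class LengthNotMultipleOfThree(MaveKitError):
    """Coding nucleotide sequence length is not divisible by three."""


class BadSpec(MaveKitError):
    """Generator specification is invalid."""


class Exhausted(MaveKitError):
    """The generator cannot draw enough distinct variants."""


class InvalidCollection(MaveKitError):
    """A record collection failed hierarchy validation where a clean one is required."""


class CorruptArchive(MaveKitError):
    """Bulk-release archive metadata is missing or unreadable."""


class EmptyScores(MaveKitError):
    """All score values are missing; a histogram cannot be built."""


class AlphabetMismatch(MaveKitError):
    """Requested effect-matrix alphabet is incompatible with the table/target."""
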