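"""MaveDB-style URN accessions.

Accessions are hierarchical: an experiment set (``urn:mavedb:00000055``)
contains experiments (``…-a``), which contain score sets (``…-a-1``), whose
individual variants are addressed with a fragment (``…-a-1#7``).  The
experiment-set number is an 8-digit zero-padded integer; experiment
suffixes are lowercase letters (a, b, …, z, aa, …); score-set and variant
indices are positive integers.  Unpublished records may use the temporary
``tmp`` namespace in place of ``urn``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import InvalidUrn, MalformedUrn

__all__ = ["Urn", "parse_urn", "format_urn"]

_URN_RE = re.compile(
    r"^(urn|tmp):mavedb:(\d{8})"
    r"(?:-([a-z]+)"
    r"(?:-([1-9]\d*)"
    r"(?:#([1-9]\d*))?"
    r")?)?$"
)

_LEVELS = ("experiment_set", "experiment", "score_set", "variant")


@dataclass(frozen=True, order=True)
class Urn:
    """A parsed accession at one of the four hierarchy levels."""

    experiment_set: int
    experiment_suffix: str | None = None
    score_set_index: int | None = None
    variant_index: int | None = None
    temporary: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.experiment_set <= 99_999_999:
            raise InvalidUrn(
                f"experiment-set number {self.experiment_set} does not fit 8 digits"
            )
        if self.experiment_suffix is not None and (
            not self.experiment_suffix
            or not self.experiment_suffix.isalpha()
            or not self.experiment_suffix.islower()
        ):
            raise InvalidUrn(
                f"experiment suffix must be lowercase letters, got "
                f"{self.experiment_suffix!r}"
            )
        if self.score_set_index is not None:
            if self.experiment_suffix is None:
                raise InvalidUrn("score-set index requires an experiment suffix")
            if self.score_set_index < 1:
                raise InvalidUrn("score-set index must be positive")
        if self.variant_index is not None:
            if self.score_set_index is None:
                raise InvalidUrn("variant index requires a score-set index")
            if self.variant_index < 1:
                raise InvalidUrn("variant index must be positive")

    @property
    def level(self) -> str:
        if self.variant_index is not None:
            return "variant"
        if self.score_set_index is not None:
            return "score_set"
        if self.experiment_suffix is not None:
            return "experiment"
        return "experiment_set"

    @property
    def parent(self) -> "Urn | None":
        """The accession one level up, or None at the experiment-set level."""
        if self.variant_index is not None:
            return Urn(self.experiment_set, self.experiment_suffix,
                       self.score_set_index, None, self.temporary)
        if self.score_set_index is not None:
            return Urn(self.experiment_set, self.experiment_suffix,
                       None, None, self.temporary)
        if self.experiment_suffix is not None:
            return Urn(self.experiment_set, None, None, None, self.temporary)
        return None

    def extends(self, ancestor: "Urn") -> bool:
        """True iff ``ancestor`` lies on this accession's parent chain."""
        u: Urn | None = self.parent
        while u is not None:
            if u == ancestor:
                return True
            u = u.parent
        return False

    def __str__(self) -> str:
        return format_urn(self)


def parse_urn(s: str) -> Urn:
    """Parse ``urn:mavedb:NNNNNNNN[-x[-k[#v]]]`` into a :class:`Urn`.

    Raises :class:`MalformedUrn` for anything else, including unpadded
    experiment-set numbers (``urn:mavedb:55``).
    """
    if not isinstance(s, str) or not s:
        raise MalformedUrn("URN must be a nonempty string")
    m = _URN_RE.match(s)
    if not m:
        raise MalformedUrn(
            f"{s!r} is not a valid accession "
            '(expected "urn:mavedb:NNNNNNNN[-x[-k[#v]]]" with 8-digit padding)'
        )
    ns, number, suffix, ss_idx, var_idx = m.groups()
    return Urn(
        experiment_set=int(number),
        experiment_suffix=suffix,
        score_set_index=int(ss_idx) if ss_idx else None,
        variant_index=int(var_idx) if var_idx else None,
        temporary=(ns == "tmp"),
    )


def format_urn(u: Urn) -> str:
    """Serialize a :class:`Urn` canonically; inverse of :func:`parse_urn`."""
    if not isinstance(u, Urn):
        raise InvalidUrn(f"expected a Urn, got {type(u).__name__}")
    parts = [f"{'tmp' if u.temporary else 'urn'}:mavedb:{u.experiment_set:08d}"]
    if u.experiment_suffix is not None:
        parts.append(f"-{u.experiment_suffix}")
        if u.score_set_index is not None:
            parts.append(f"-{u.score_set_index}")
            if u.variant_index is not None:
                parts.append(f"#{u.variant_index}")
    return "".join(parts)
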