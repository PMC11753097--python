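"""Strict parser and formatter for the MAVE-HGVS variant dialect.

MAVE-HGVS is a strictly validatable subset of the HGVS sequence-variant
nomenclature used for multiplexed-assay targets, which typically lack
database reference sequences.  The subset implemented here covers
substitution, deletion, duplication, insertion, deletion-insertion and the
target-identical variant ("=") under the ``g.``/``c.``/``n.`` (nucleotide)
and ``p.`` (protein) prefixes, including multi-event variants written as
``c.[1A>G;5del]``.

Deliberately outside the subset (raising :class:`UnsupportedFeature`):
uncertainty notation (``?``, parenthesised predictions), frameshift
shorthand, repeats, multi-molecule alleles, mosaicism, and the legacy
Enrich2 tokens ``_wt``/``_sy`` that predate this nomenclature.

Coordinates are 1-based fully closed.  Offset (intronic) positions such as
``122-6`` are accepted only when parsing in splice context, because they
cannot be checked against a contiguous target sequence.  Amino acids must
use three-letter codes (``Trp``, ``Ter``); one-letter input is rejected
rather than auto-converted so that round-trips are unambiguous.

The canonical form of a variant is exactly the set of strings this parser
accepts: ``format_variant(parse_variant(s)) == s`` for every accepted ``s``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum

from .errors import (
    InvalidVariant,
    MalformedVariant,
    OffsetNotAllowed,
    UnsupportedFeature,
)

__all__ = [
    "AA_CODES",
    "EventKind",
    "Position",
    "Variant",
    "VariantEvent",
    "covered_positions",
    "format_variant",
    "parse_variant",
]

#: Three-letter amino-acid codes accepted under the ``p.`` prefix.
#: ``Ter`` denotes the translation stop.
AA_CODES = (
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
    "Ter",
)

_NT = "ACGT"
_AA_ALT = "|".join(AA_CODES)

# index without leading zeros; optional signed offset without leading zeros
_POS = r"([1-9]\d*)([+-][1-9]\d*)?"
_AA_POS = rf"({_AA_ALT})([1-9]\d*)"

_NT_SUB = re.compile(rf"^{_POS}([{_NT}])>([{_NT}])$")
_NT_DELINS = re.compile(rf"^{_POS}(?:_{_POS})?delins([{_NT}]+)$")
_NT_DELDUP = re.compile(rf"^{_POS}(?:_{_POS})?(del|dup)$")
_NT_INS = re.compile(rf"^{_POS}_{_POS}ins([{_NT}]+)$")

_P_SUB = re.compile(rf"^{_AA_POS}({_AA_ALT})$")
_P_DELINS = re.compile(rf"^{_AA_POS}(?:_{_AA_POS})?delins((?:{_AA_ALT})+)$")
_P_DELDUP = re.compile(rf"^{_AA_POS}(?:_{_AA_POS})?(del|dup)$")
_P_INS = re.compile(rf"^{_AA_POS}_{_AA_POS}ins((?:{_AA_ALT})+)$")

_AA_TOKEN = re.compile(_AA_ALT)

_LEGACY_TOKENS = ("_wt", "_sy")


class EventKind(str, Enum):
    SUBSTITUTION = "substitution"
    DELETION = "deletion"
    DUPLICATION = "duplication"
    INSERTION = "insertion"
    DELINS = "delins"
    IDENTICAL = "identical"


@dataclass(frozen=True, order=True)
class Position:
    """A 1-based target coordinate with an optional intronic offset.

    ``offset`` orders positions sharing an anchor index: ``122-6`` sorts
    before ``122`` which sorts before ``122+3``.
    """

    index: int
    offset: int = 0

    def __post_init__(self) -> None:
        if self.index < 1:
            raise InvalidVariant(f"position index must be >= 1, got {self.index}")

    def __str__(self) -> str:
        if self.offset == 0:
            return str(self.index)
        return f"{self.index}{self.offset:+d}"


@dataclass(frozen=True)
class VariantEvent:
    """One edit event within a variant.

    ``ref`` holds the reference residues *stated in the string*: the single
    reference base/residue for substitutions, the stated start/end residues
    for protein deletions, duplications and delins (one or two three-letter
    tokens), and the two flanking residues for protein insertions.
    Nucleotide deletion/duplication/insertion/delins strings state no
    reference residues, so ``ref`` is empty there.
    """

    kind: EventKind
    start: Position
    end: Position
    ref: str = ""
    alt: str = ""

    @property
    def is_range(self) -> bool:
        return (self.start.index, self.start.offset) != (self.end.index, self.end.offset)


@dataclass(frozen=True)
class Variant:
    """A parsed MAVE-HGVS variant: prefix plus one or more ordered events."""

    prefix: str
    events: tuple[VariantEvent, ...]
    raw: str = ""

    @property
    def is_protein(self) -> bool:
        return self.prefix == "p"

    @property
    def is_multi(self) -> bool:
        return len(self.events) > 1

    def __str__(self) -> str:
        return format_variant(self)


def _check_offsets(pos: Position, splice_context: bool, at: int) -> None:
    if pos.offset != 0 and not splice_context:
        raise OffsetNotAllowed(
            "offset positions are only valid in splice context (hgvs_splice)", at
        )


def _mkpos(idx: str, off: str | None) -> Position:
    return Position(int(idx), int(off) if off else 0)


def _parse_nt_event(body: str, at: int, splice_context: bool) -> VariantEvent:
    m = _NT_SUB.match(body)
    if m:
        start = _mkpos(m.group(1), m.group(2))
        _check_offsets(start, splice_context, at)
        ref, alt = m.group(3), m.group(4)
        if ref == alt:
            raise MalformedVariant(
                "reference and alternate bases are equal; "
                'the target-identical variant must be written "="',
                at,
            )
        return VariantEvent(EventKind.SUBSTITUTION, start, start, ref, alt)

    m = _NT_DELINS.match(body)
    if m:
        start = _mkpos(m.group(1), m.group(2))
        end = _mkpos(m.group(3), m.group(4)) if m.group(3) else start
        _check_offsets(start, splice_context, at)
        _check_offsets(end, splice_context, at)
        if m.group(3) and end <= start:
            raise MalformedVariant("range end must be greater than range start", at)
        return VariantEvent(EventKind.DELINS, start, end, "", m.group(5))

    m = _NT_DELDUP.match(body)
    if m:
        start = _mkpos(m.group(1), m.group(2))
        end = _mkpos(m.group(3), m.group(4)) if m.group(3) else start
        _check_offsets(start, splice_context, at)
        _check_offsets(end, splice_context, at)
        if m.group(3) and end <= start:
            raise MalformedVariant("range end must be greater than range start", at)
        kind = EventKind.DELETION if m.group(5) == "del" else EventKind.DUPLICATION
        return VariantEvent(kind, start, end)

    m = _NT_INS.match(body)
    if m:
        start = _mkpos(m.group(1), m.group(2))
        end = _mkpos(m.group(3), m.group(4))
        _check_offsets(start, splice_context, at)
        _check_offsets(end, splice_context, at)
        if start.offset == 0 and end.offset == 0:
            if end.index != start.index + 1:
                raise MalformedVariant(
                    "insertion flanks must be adjacent positions", at
                )
        elif end <= start:
            raise MalformedVariant("insertion flanks must be in ascending order", at)
        return VariantEvent(EventKind.INSERTION, start, end, "", m.group(5))

    raise MalformedVariant(f"unrecognized nucleotide event {body!r}", at)


def _parse_protein_event(body: str, at: int) -> VariantEvent:
    m = _P_SUB.match(body)
    if m:
        ref, idx, alt = m.group(1), m.group(2), m.group(3)
        if ref == alt:
            raise MalformedVariant(
                "reference and alternate residues are equal; "
                'the target-identical variant must be written "="',
                at,
            )
        pos = Position(int(idx))
        return VariantEvent(EventKind.SUBSTITUTION, pos, pos, ref, alt)

    m = _P_DELINS.match(body)
    if m:
        start = Position(int(m.group(2)))
        if m.group(3):
            end = Position(int(m.group(4)))
            if end <= start:
                raise MalformedVariant("range end must be greater than range start", at)
            ref = m.group(1) + m.group(3)
        else:
            end, ref = start, m.group(1)
        return VariantEvent(EventKind.DELINS, start, end, ref, m.group(5))

    m = _P_DELDUP.match(body)
    if m:
        start = Position(int(m.group(2)))
        if m.group(3):
            end = Position(int(m.group(4)))
            if end <= start:
                raise MalformedVariant("range end must be greater than range start", at)
            ref = m.group(1) + m.group(3)
        else:
            end, ref = start, m.group(1)
        kind = EventKind.DELETION if m.group(5) == "del" else EventKind.DUPLICATION
        return VariantEvent(kind, start, end, ref)

    m = _P_INS.match(body)
    if m:
        start = Position(int(m.group(2)))
        end = Position(int(m.group(4)))
        if end.index != start.index + 1:
            raise MalformedVariant("insertion flanks must be adjacent residues", at)
        return VariantEvent(EventKind.INSERTION, start, end, m.group(1) + m.group(3), m.group(5))

    if re.match(r"^[A-Z]\d", body) or re.match(rf"^({_AA_ALT})\d+[A-Z]\d*$", body):
        raise MalformedVariant(
            f"unrecognized protein event {body!r}; "
            "amino acids must use three-letter codes (e.g. Trp, Ter)",
            at,
        )
    raise MalformedVariant(f"unrecognized protein event {body!r}", at)


def parse_variant(s: str, splice_context: bool = False) -> Variant:
    """Parse a MAVE-HGVS variant string into a :class:`Variant`.

    Parameters
    ----------
    s:
        Variant string, e.g. ``"c.1A>G"``, ``"p.Trp24Cys"``,
        ``"c.[1A>G;5del]"``, ``"c.="``.
    splice_context:
        Permit intronic offset positions (``122-6``).  Used when parsing
        the ``hgvs_splice`` table column; everywhere else offsets raise
        :class:`OffsetNotAllowed`.

    Raises
    ------
    MalformedVariant
        Syntax violation, with the character position of the problem.
    UnsupportedFeature
        Valid full-HGVS (or legacy Enrich2) notation outside the strict
        subset, e.g. uncertainty ``?`` or parentheses.
    OffsetNotAllowed
        Offset position with ``splice_context=False``.
    """
    if not isinstance(s, str) or not s:
        raise MalformedVariant("variant string must be a nonempty string")

    for ch, why in (("?", "uncertainty"), ("(", "predicted/uncertain notation"),
                    (")", "predicted/uncertain notation"), ("=/", "mosaicism"),
                    ("//", "chimerism")):
        at = s.find(ch)
        if at != -1:
            raise UnsupportedFeature(
                f"{why} ({ch!r}) is valid HGVS but outside the strict subset", at
            )
    for tok in _LEGACY_TOKENS:
        at = s.find(tok)
        if at != -1:
            raise UnsupportedFeature(
                f"{tok!r} is a legacy Enrich2 token, not valid in this dialect; "
                'use "=" for the target-identical variant',
                at,
            )

    if len(s) < 2 or s[1] != "." or s[0] not in "gcnp":
        if s[0].isalpha() and s[0].lower() in "gcnp" and len(s) > 1 and s[1] == ".":
            raise MalformedVariant("prefix letter must be lowercase", 0)
        raise MalformedVariant('expected prefix "g.", "c.", "n." or "p."', 0)
    prefix = s[0]
    body = s[2:]
    if not body:
        raise MalformedVariant("missing variant description after prefix", 2)

    if body == "=":
        pos = Position(1)
        return Variant(prefix, (VariantEvent(EventKind.IDENTICAL, pos, pos),), s)

    if body.startswith("["):
        if not body.endswith("]"):
            raise MalformedVariant("unterminated multi-variant bracket", len(s) - 1)
        inner = body[1:-1]
        parts = inner.split(";")
        if len(parts) < 2:
            raise MalformedVariant(
                "multi-variant brackets require at least two events", 2
            )
        events = []
        at = 3  # character offset of the first event
        for part in parts:
            if not part:
                raise MalformedVariant("empty event in multi-variant", at)
            if part == "=":
                raise MalformedVariant(
                    'the target-identical variant "=" cannot appear in a multi-variant', at
                )
            if prefix == "p":
                events.append(_parse_protein_event(part, at))
            else:
                events.append(_parse_nt_event(part, at, splice_context))
            at += len(part) + 1
        _check_event_order(events, s)
        return Variant(prefix, tuple(events), s)

    if prefix == "p":
        ev = _parse_protein_event(body, 2)
    else:
        ev = _parse_nt_event(body, 2, splice_context)
    return Variant(prefix, (ev,), s)


def _check_event_order(events: list[VariantEvent], s: str) -> None:
    for prev, cur in zip(events, events[1:]):
        if cur.start.index == prev.start.index and cur.start.offset == prev.start.offset:
            raise MalformedVariant(
                f"events at the same start position cannot co-occur in {s!r}"
            )
        if (cur.start.index, cur.start.offset) < (prev.start.index, prev.start.offset):
            raise MalformedVariant(
                f"multi-variant events must be in ascending position order in {s!r}"
            )
    spans = []
    for ev in events:
        if ev.kind in (EventKind.INSERTION, EventKind.IDENTICAL):
            continue
        spans.append((ev.start.index, ev.end.index))
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise MalformedVariant(
                f"multi-variant events cover overlapping positions in {s!r}"
            )


def _check_variant(v: Variant) -> None:
    if v.prefix not in "gcnp":
        raise InvalidVariant(f"invalid prefix {v.prefix!r}")
    if not v.events:
        raise InvalidVariant("variant must have at least one event")
    tokens_ok = _is_protein_tokens if v.prefix == "p" else _is_nt_tokens
    for ev in v.events:
        if ev.end < ev.start:
            raise InvalidVariant("event end precedes start")
        if not tokens_ok(ev.ref) or not tokens_ok(ev.alt):
            raise InvalidVariant(
                f"ref/alt tokens incompatible with prefix {v.prefix!r}: "
                f"{ev.ref!r}/{ev.alt!r}"
            )
        if ev.kind is EventKind.SUBSTITUTION:
            n = 3 if v.prefix == "p" else 1
            if len(ev.ref) != n or len(ev.alt) != n or ev.ref == ev.alt:
                raise InvalidVariant("substitution requires one ref and one differing alt token")
        elif ev.kind is EventKind.INSERTION:
            if not ev.alt:
                raise InvalidVariant("insertion requires inserted residues")
            if v.prefix != "p" and ev.ref:
                raise InvalidVariant("nucleotide insertion states no reference residues")
        elif ev.kind is EventKind.IDENTICAL:
            if ev.ref or ev.alt:
                raise InvalidVariant("identical event carries no residues")
            if len(v.events) > 1:
                raise InvalidVariant("identical event must be the only event")
    if len(v.events) > 1:
        try:
            _check_event_order(list(v.events), "<variant>")
        except MalformedVariant as e:
            raise InvalidVariant(str(e)) from e


def _is_nt_tokens(tok: str) -> bool:
    return all(c in _NT for c in tok)


def _is_protein_tokens(tok: str) -> bool:
    if len(tok) % 3:
        return False
    return all(tok[i:i + 3] in AA_CODES for i in range(0, len(tok), 3))


def _format_event(ev: VariantEvent, protein: bool) -> str:
    if ev.kind is EventKind.IDENTICAL:
        return "="
    if protein:
        start = f"{ev.ref[:3]}{ev.start}" if ev.ref else str(ev.start)
        if ev.kind is EventKind.SUBSTITUTION:
            return f"{start}{ev.alt}"
        if ev.kind in (EventKind.INSERTION,) or ev.is_range:
            end = f"{ev.ref[3:6]}{ev.end}"
            loc = f"{start}_{end}"
        else:
            loc = start
        if ev.kind is EventKind.DELETION:
            return f"{loc}del"
        if ev.kind is EventKind.DUPLICATION:
            return f"{loc}dup"
        if ev.kind is EventKind.INSERTION:
            return f"{loc}ins{ev.alt}"
        return f"{loc}delins{ev.alt}"
    # nucleotide
    if ev.kind is EventKind.SUBSTITUTION:
        return f"{ev.start}{ev.ref}>{ev.alt}"
    loc = f"{ev.start}_{ev.end}" if ev.is_range or ev.kind is EventKind.INSERTION else str(ev.start)
    if ev.kind is EventKind.DELETION:
        return f"{loc}del"
    if ev.kind is EventKind.DUPLICATION:
        return f"{loc}dup"
    if ev.kind is EventKind.INSERTION:
        return f"{loc}ins{ev.alt}"
    return f"{loc}delins{ev.alt}"


def format_variant(v: Variant) -> str:
    """Serialize a :class:`Variant` to its canonical string.

    ``parse_variant(format_variant(v))`` reproduces ``v`` event-for-event.
    Raises :class:`InvalidVariant` if ``v`` violates its invariants.
    """
    _check_variant(v)
    protein = v.prefix == "p"
    parts = [_format_event(ev, protein) for ev in v.events]
    if len(parts) == 1:
        return f"{v.prefix}.{parts[0]}"
    return f"{v.prefix}.[{';'.join(parts)}]"


def covered_positions(v: Variant) -> set[int]:
    """Target positions whose reference residue the variant asserts or removes.

    The union of the closed ranges ``[start, end]`` over all events, except
    that insertions (which sit *between* reference positions) and the
    target-identical event contribute nothing.  Raises
    :class:`OffsetNotAllowed` if any position carries an intronic offset,
    since offset positions do not map onto the contiguous target.
    """
    out: set[int] = set()
    for ev in v.events:
        if ev.start.offset or ev.end.offset:
            raise OffsetNotAllowed("covered positions are undefined for offset positions")
        if ev.kind in (EventKind.INSERTION, EventKind.IDENTICAL):
            continue
        out.update(range(ev.start.index, ev.end.index + 1))
    return out
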