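"""Consistency checks between parsed variants and a target sequence.

A score set in this data model is defined against its own target sequence
(nucleotide or protein); a variant string is only meaningful if the
reference residues it states actually occur at the stated positions of that
target.  This module performs those checks directly against a
:class:`TargetSequence`, or against an external accession through a
pluggable :class:`SequenceLookup` — the mode used for assays such as
saturation genome editing that anchor variants to a transcript or genome
accession rather than a local target.

Protein-level (``p.``) variants can be validated against a coding
nucleotide target by translating it with the standard codon table.
Splice-column variants carrying intronic offsets receive format-only
validation (finding code ``FORMAT_ONLY``, info severity): without a genome
there is nothing to check intronic bases against.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, runtime_checkable

from Bio import SeqIO
from Bio.Seq import Seq

from .errors import BadAlphabet, LengthNotMultipleOfThree
from .grammar import AA_CODES, EventKind, Variant, VariantEvent
from .report import ValidationReport

__all__ = [
    "AA3_TO_1",
    "AA1_TO_3",
    "DictLookup",
    "FastaLookup",
    "SequenceLookup",
    "TargetSequence",
    "read_fasta_targets",
    "translate_dna",
    "validate_against_accession",
    "validate_against_target",
]

_NT_ALPHABET = set("ACGT")
_AA1 = "ARNDCQEGHILKMFPSTWYV"
_PROTEIN_ALPHABET = set(_AA1) | {"*"}

#: Three-letter ↔ one-letter amino-acid code maps (Ter ↔ ``*``).
AA3_TO_1 = dict(zip(AA_CODES, list(_AA1) + ["*"]))
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}


@dataclass(frozen=True)
class TargetSequence:
    """A labeled target sequence a score set is defined against.

    ``kind`` is ``"nucleotide"`` or ``"protein"``; protein sequences use
    one-letter codes with ``*`` allowed as a terminal stop.  ``category``
    describes the functional element (coding, non_coding, regulatory,
    other); protein-level validation against a nucleotide target is only
    possible for coding targets.
    """

    label: str
    kind: str
    sequence: str
    category: str = "other"

    def __post_init__(self) -> None:
        if self.kind not in ("nucleotide", "protein"):
            raise ValueError(f"unknown target kind {self.kind!r}")
        if self.category not in ("coding", "non_coding", "regulatory", "other"):
            raise ValueError(f"unknown target category {self.category!r}")
        if not self.sequence:
            raise BadAlphabet("target sequence must be nonempty")
        alphabet = _NT_ALPHABET if self.kind == "nucleotide" else _PROTEIN_ALPHABET
        bad = set(self.sequence) - alphabet
        if bad:
            raise BadAlphabet(
                f"target {self.label!r} contains characters outside the "
                f"{self.kind} alphabet: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_coding(self) -> bool:
        return self.kind == "nucleotide" and self.category == "coding"

    def protein(self) -> str:
        """The protein-level sequence: itself, or the translation if coding."""
        if self.kind == "protein":
            return self.sequence
        if not self.is_coding:
            raise ValueError(
                f"target {self.label!r} is non-coding; it has no protein level"
            )
        return translate_dna(self.sequence)


def translate_dna(seq: str) -> str:
    """Translate coding DNA with the standard codon table.

    Internal stop codons translate to ``*`` (callers downstream emit a
    warning finding for them).  Raises :class:`BadAlphabet` for characters
    outside ACGT and :class:`LengthNotMultipleOfThree` when the length is
    not divisible by three.
    """
    bad = set(seq) - _NT_ALPHABET
    if bad:
        raise BadAlphabet(f"sequence contains non-ACGT characters: {sorted(bad)}")
    if len(seq) % 3:
        raise LengthNotMultipleOfThree(
            f"coding sequence length {len(seq)} is not a multiple of three"
        )
    return str(Seq(seq).translate())


@runtime_checkable
class SequenceLookup(Protocol):
    """Resolves an accession and 1-based closed interval to reference residues.

    Implementations must be deterministic for a fixed accession/interval and
    return ``None`` when the accession or interval cannot be resolved.
    """

    def fetch(self, accession: str, start: int, end: int) -> str | None:
        ...


class DictLookup:
    """In-memory :class:`SequenceLookup` over ``{accession: sequence}``."""

    def __init__(self, sequences: dict[str, str]):
        self._sequences = dict(sequences)

    def fetch(self, accession: str, start: int, end: int) -> str | None:
        seq = self._sequences.get(accession)
        if seq is None or start < 1 or end > len(seq) or end < start:
            return None
        return seq[start - 1:end]


class FastaLookup(DictLookup):
    """:class:`SequenceLookup` backed by a local FASTA file (ids are accessions)."""

    def __init__(self, path: str | Path):
        records = SeqIO.parse(str(path), "fasta")
        super().__init__({r.id: str(r.seq).upper() for r in records})


def read_fasta_targets(path: str | Path, kind: str | None = None,
                       category: str = "other") -> list[TargetSequence]:
    """Read one or more targets from a FASTA file; record ids become labels.

    When ``kind`` is None it is inferred per record: sequences drawn
    entirely from ACGT are nucleotide, anything else protein.
    """
    targets = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        k = kind or ("nucleotide" if set(seq) <= _NT_ALPHABET else "protein")
        targets.append(TargetSequence(rec.id, k, seq, category))
    return targets


def _check_stated_refs(ev: VariantEvent, seq: str, protein: bool,
                       report: ValidationReport) -> None:
    """Compare the reference residues stated by one event against ``seq``."""
    if protein:
        checks = []
        if ev.kind is EventKind.SUBSTITUTION:
            checks.append((ev.start.index, ev.ref))
        elif ev.ref:
            checks.append((ev.start.index, ev.ref[:3]))
            if len(ev.ref) > 3:
                checks.append((ev.end.index, ev.ref[3:6]))
        for idx, tok in checks:
            actual = seq[idx - 1]
            if AA3_TO_1[tok] != actual:
                report.error(
                    "REF_MISMATCH",
                    f"variant states {tok} at position {idx} but target has "
                    f"{AA1_TO_3.get(actual, actual)}",
                    locus=idx,
                )
    else:
        if ev.kind is EventKind.SUBSTITUTION and ev.ref:
            actual = seq[ev.start.index - 1]
            if ev.ref != actual:
                report.error(
                    "REF_MISMATCH",
                    f"variant states {ev.ref} at position {ev.start.index} "
                    f"but target has {actual}",
                    locus=ev.start.index,
                )


def _validate_events(v: Variant, seq: str, protein: bool) -> ValidationReport:
    report = ValidationReport()
    n = len(seq)
    for ev in v.events:
        if ev.start.offset or ev.end.offset:
            report.info(
                "FORMAT_ONLY",
                "offset (intronic) positions cannot be checked against a "
                "contiguous target; format-only validation applied",
            )
            continue
        if ev.kind is EventKind.IDENTICAL:
            continue
        # bounds first; a position off the end has no residue to compare
        if ev.end.index > n or ev.start.index > n:
            report.error(
                "OUT_OF_BOUNDS",
                f"event spans position {max(ev.start.index, ev.end.index)} "
                f"but the target has length {n}",
                locus=max(ev.start.index, ev.end.index),
            )
            continue
        _check_stated_refs(ev, seq, protein, report)
    return report


def validate_against_target(v: Variant, t: TargetSequence) -> ValidationReport:
    """Validate a parsed variant against a local target sequence.

    Checks prefix/kind compatibility (``p.`` needs a protein level —
    supplied directly or by translating a coding nucleotide target;
    ``g.``/``c.``/``n.`` need a nucleotide target), position bounds, and
    agreement of every stated reference residue with the target.  All
    problems are returned as findings; nothing raises on bad data.
    """
    report = ValidationReport()
    if v.prefix == "p":
        if t.kind == "protein":
            seq = t.sequence
        elif t.is_coding:
            seq = translate_dna(t.sequence)
            if "*" in seq[:-1]:
                report.warning(
                    "INTERNAL_STOP",
                    "translated coding target contains an internal stop codon",
                    locus=seq.index("*") + 1,
                )
        else:
            report.error(
                "PREFIX_TARGET_MISMATCH",
                f"protein-level variant cannot be validated against "
                f"{t.category} {t.kind} target {t.label!r}",
            )
            return report
        # a terminal stop, if present, is an addressable position (Ter)
        report.extend(_validate_events(v, seq, True))
    else:
        if t.kind != "nucleotide":
            report.error(
                "PREFIX_TARGET_MISMATCH",
                f"nucleotide-level variant ({v.prefix}.) cannot be validated "
                f"against protein target {t.label!r}",
            )
            return report
        report.extend(_validate_events(v, t.sequence, False))
    return report


def validate_against_accession(v: Variant, accession: str,
                               lookup: SequenceLookup) -> ValidationReport:
    """Validate a variant against an accession through a sequence lookup.

    Runs the same stated-reference checks as :func:`validate_against_target`
    on lookup-fetched slices.  An unresolvable accession or interval yields
    an ``UNRESOLVED_ACCESSION`` error finding rather than an exception.
    """
    report = ValidationReport()
    protein = v.prefix == "p"
    for ev in v.events:
        if ev.start.offset or ev.end.offset:
            report.info(
                "FORMAT_ONLY",
                "offset (intronic) positions receive format-only validation "
                "in accession mode",
            )
            continue
        if ev.kind is EventKind.IDENTICAL:
            continue
        slice_ = lookup.fetch(accession, ev.start.index, ev.end.index)
        if slice_ is None:
            report.error(
                "UNRESOLVED_ACCESSION",
                f"could not resolve {accession}:{ev.start.index}-{ev.end.index}",
                locus=ev.start.index,
            )
            continue
        # re-anchor the fetched slice so stated positions index into it
        pad = "?" * (ev.start.index - 1)
        _check_stated_refs(ev, pad + slice_, protein, report)
    return report
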