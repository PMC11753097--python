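"""Shared fixtures and an independent canonical variant-string builder.

``random_canonical_variant`` constructs canonical MAVE-HGVS strings by
direct string assembly from the grammar rules — never via the package's
formatter — so round-trip tests check the parser/formatter pair against an
independent oracle.
"""

from __future__ import annotations

import numpy as np
import pytest

from mavekit.grammar import AA_CODES
from mavekit.target_check import TargetSequence

AA20 = [a for a in AA_CODES if a != "Ter"]
NT = "ACGT"


def _nt_event(rng: np.random.Generator, lo: int = 1, hi: int = 500) -> tuple[int, int, str]:
    """Return (start, end, text) for one canonical nucleotide event."""
    kind = rng.choice(["sub", "del", "dup", "ins", "delins"],
                      p=[0.4, 0.2, 0.1, 0.1, 0.2])
    start = int(rng.integers(lo, hi))
    if kind == "sub":
        ref, alt = rng.choice(list(NT), size=2, replace=False)
        return start, start, f"{start}{ref}>{alt}"
    if kind == "ins":
        ins = "".join(rng.choice(list(NT), size=int(rng.integers(1, 5))))
        return start, start + 1, f"{start}_{start + 1}ins{ins}"
    end = start + int(rng.integers(0, 5))
    loc = str(start) if end == start else f"{start}_{end}"
    if kind == "del":
        return start, end, f"{loc}del"
    if kind == "dup":
        return start, end, f"{loc}dup"
    ins = "".join(rng.choice(list(NT), size=int(rng.integers(1, 5))))
    return start, end, f"{loc}delins{ins}"


def _protein_event(rng: np.random.Generator, lo: int = 1, hi: int = 500) -> tuple[int, int, str]:
    kind = rng.choice(["sub", "del", "dup", "ins", "delins"],
                      p=[0.4, 0.2, 0.1, 0.1, 0.2])
    start = int(rng.integers(lo, hi))
    a1 = rng.choice(AA20)
    if kind == "sub":
        alt = rng.choice([a for a in AA_CODES if a != a1])
        return start, start, f"{a1}{start}{alt}"
    if kind == "ins":
        a2 = rng.choice(AA20)
        ins = "".join(rng.choice(AA20, size=int(rng.integers(1, 4))))
        return start, start + 1, f"{a1}{start}_{a2}{start + 1}ins{ins}"
    end = start + int(rng.integers(0, 5))
    if end == start:
        loc = f"{a1}{start}"
    else:
        a2 = rng.choice(AA20)
        loc = f"{a1}{start}_{a2}{end}"
    if kind == "del":
        return start, end, f"{loc}del"
    if kind == "dup":
        return start, end, f"{loc}dup"
    ins = "".join(rng.choice(AA20, size=int(rng.integers(1, 4))))
    return start, end, f"{loc}delins{ins}"


def random_canonical_variant(rng: np.random.Generator) -> str:
    """Build one canonical variant string by direct assembly."""
    prefix = rng.choice(["g", "c", "n", "p"])
    if rng.random() < 0.03:
        return f"{prefix}.="
    make = _protein_event if prefix == "p" else _nt_event
    if rng.random() < 0.2:
        # multi-variant: ascending, non-overlapping, gap between events
        n = int(rng.integers(2, 4))
        parts, cursor = [], 1
        for _ in range(n):
            start, end, text = make(rng, cursor, cursor + 40)
            parts.append(text)
            cursor = end + 2
        return f"{prefix}.[{';'.join(parts)}]"
    _, _, text = make(rng)
    return f"{prefix}.{text}"


@pytest.fixture
def mwc_protein() -> TargetSequence:
    return TargetSequence("mwc", "protein", "MWC")


@pytest.fixture
def mwc_coding() -> TargetSequence:
    # translates to MWC under the standard codon table
    return TargetSequence("mwc_dna", "nucleotide", "ATGTGGTGC", "coding")


@pytest.fixture
def atg_target() -> TargetSequence:
    return TargetSequence("atg", "nucleotide", "ATG", "non_coding")
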