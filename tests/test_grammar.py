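"""Parser/formatter behaviour for the strict MAVE-HGVS subset."""

import numpy as np
import pytest

from mavekit.errors import (
    InvalidVariant,
    MalformedVariant,
    OffsetNotAllowed,
    UnsupportedFeature,
    VariantSyntaxError,
)
from mavekit.grammar import (
    EventKind,
    Position,
    Variant,
    VariantEvent,
    covered_positions,
    format_variant,
    parse_variant,
)

from conftest import random_canonical_variant


class TestParse:
    def test_nucleotide_substitution(self):
        v = parse_variant("c.1A>G")
        assert v.prefix == "c" and len(v.events) == 1
        ev = v.events[0]
        assert ev.kind is EventKind.SUBSTITUTION
        assert ev.start.index == 1 and ev.ref == "A" and ev.alt == "G"

    def test_protein_substitution_three_letter(self):
        v = parse_variant("p.Trp24Cys")
        ev = v.events[0]
        assert v.prefix == "p" and ev.start.index == 24
        assert ev.ref == "Trp" and ev.alt == "Cys"

    def test_multi_variant_kinds(self):
        v = parse_variant("c.[1A>G;5del]")
        assert [e.kind for e in v.events] == [EventKind.SUBSTITUTION,
                                              EventKind.DELETION]

    def test_identity_written_as_equals(self):
        v = parse_variant("c.=")
        assert v.events[0].kind is EventKind.IDENTICAL
        with pytest.raises(MalformedVariant):
            parse_variant("c.1A>A")  # identity must be written "c.="

    def test_splice_offset_positions(self):
        v = parse_variant("c.122-6T>A", splice_context=True)
        assert v.events[0].start.offset == -6
        with pytest.raises(OffsetNotAllowed):
            parse_variant("c.122-6T>A", splice_context=False)

    @pytest.mark.parametrize("s,kind", [
        ("c.5_7del", EventKind.DELETION),
        ("c.5_7dup", EventKind.DUPLICATION),
        ("c.5_6insTTT", EventKind.INSERTION),
        ("c.5_7delinsAAA", EventKind.DELINS),
        ("p.Cys3del", EventKind.DELETION),
        ("p.Cys3_Glu5del", EventKind.DELETION),
        ("p.Cys3dup", EventKind.DUPLICATION),
        ("p.Cys3_Glu4insTrpGln", EventKind.INSERTION),
        ("p.Cys3delinsTrpGln", EventKind.DELINS),
        ("g.44dup", EventKind.DUPLICATION),
        ("n.12G>T", EventKind.SUBSTITUTION),
    ])
    def test_event_kinds(self, s, kind):
        assert parse_variant(s).events[0].kind is kind

    @pytest.mark.parametrize("bad", [
        "", "c.", "x.1A>G", "C.1A>G", "c.0A>G", "c.01A>G", "c.1a>g",
        "c.1A>", "c.1>G", "c.A>G", "c.1A>A", "c.5_5del", "c.7_5del",
        "c.5_7insTTT", "c.5_6ins", "p.W24C", "p.Trp24", "p.Trp24Trp",
        "c.[1A>G]", "c.[1A>G;;5del]", "c.[1A>G;5del", "c.[5del;1A>G]",
        "c.[1A>G;1A>T]", "c.[1A>G;=]", "c.1_2A>G", "c.1insA",
    ])
    def test_rejected_strings(self, bad):
        with pytest.raises(MalformedVariant):
            parse_variant(bad)

    @pytest.mark.parametrize("bad", ["c.1A>?", "c.(1A>G)", "p.(Trp24Cys)",
                                     "_wt", "_sy", "c._wt"])
    def test_unsupported_features_named(self, bad):
        with pytest.raises(UnsupportedFeature):
            parse_variant(bad)

    def test_legacy_enrich2_message_names_the_format(self):
        with pytest.raises(UnsupportedFeature, match="Enrich2"):
            parse_variant("_sy")

    def test_error_carries_character_position(self):
        with pytest.raises(MalformedVariant) as exc:
            parse_variant("c.1A>")
        assert exc.value.position is not None

    def test_overlapping_multi_events_rejected(self):
        with pytest.raises(MalformedVariant):
            parse_variant("c.[1_5del;3A>G]")
        with pytest.raises(MalformedVariant):
            parse_variant("c.[1A>G;1del]")  # equal starts cannot co-occur


class TestFormat:
    def test_identity(self):
        pos = Position(1)
        v = Variant("c", (VariantEvent(EventKind.IDENTICAL, pos, pos),))
        assert format_variant(v) == "c.="

    def test_protein_substitution(self):
        pos = Position(24)
        v = Variant("p", (VariantEvent(EventKind.SUBSTITUTION, pos, pos,
                                       "Trp", "Cys"),))
        assert format_variant(v) == "p.Trp24Cys"

    def test_invalid_variant_rejected(self):
        pos = Position(1)
        v = Variant("p", (VariantEvent(EventKind.SUBSTITUTION, pos, pos,
                                       "Trp", "Trp"),))
        with pytest.raises(InvalidVariant):
            format_variant(v)
        v = Variant("c", (VariantEvent(EventKind.SUBSTITUTION, pos, pos,
                                       "Trp", "Cys"),))
        with pytest.raises(InvalidVariant):
            format_variant(v)


class TestRoundTrip:
    def test_round_trip_sample(self):
        """format∘parse is the identity on independently built canonical strings."""
        rng = np.random.default_rng(42)
        for _ in range(2000):
            s = random_canonical_variant(rng)
            v = parse_variant(s)
            assert format_variant(v) == s
            # event-for-event reproduction through a second cycle
            assert parse_variant(format_variant(v)).events == v.events

    def test_single_character_fuzz_never_crashes(self):
        rng = np.random.default_rng(43)
        alphabet = list("gcnp.[]_;>=0123456789ACGTacgtTrpXy*?+-(")
        for _ in range(500):
            s = random_canonical_variant(rng)
            i = int(rng.integers(len(s)))
            mutant = s[:i] + str(rng.choice(alphabet)) + s[i + 1:]
            try:
                v = parse_variant(mutant)
                assert format_variant(v) == mutant
            except VariantSyntaxError:
                pass  # a declared error is the expected outcome


class TestCoveredPositions:
    @pytest.mark.parametrize("s,expected", [
        ("c.5_7del", {5, 6, 7}),
        ("c.5_6insTTT", set()),
        ("c.[1A>G;5del]", {1, 5}),
        ("c.=", set()),
        ("p.Cys3_Glu5dup", {3, 4, 5}),
    ])
    def test_examples(self, s, expected):
        assert covered_positions(parse_variant(s)) == expected

    def test_offset_positions_rejected(self):
        v = parse_variant("c.122-6T>A", splice_context=True)
        with pytest.raises(OffsetNotAllowed):
            covered_positions(v)


class TestPropertyBased:
    """Hypothesis-driven round-trip over the canonical-string space."""

    from hypothesis import given, settings, strategies as st

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_round_trip_any_seed(self, seed):
        rng = np.random.default_rng(seed)
        s = random_canonical_variant(rng)
        assert format_variant(parse_variant(s)) == s
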