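"""URN accessions, table schema validation, and the record hierarchy."""

import numpy as np
import pytest

from mavekit.errors import InvalidUrn, MalformedUrn
from mavekit.records import (
    ExperimentRecord,
    ExperimentSetRecord,
    RecordCollection,
    Reference,
    ScoreSetRecord,
    validate_hierarchy,
)
from mavekit.report import Severity
from mavekit.synth import GeneratorSpec, make_collection
from mavekit.tables import (
    CountTable,
    ScoreTable,
    validate_count_consistency,
    validate_score_table,
)
from mavekit.urn import Urn, format_urn, parse_urn


class TestUrn:
    def test_printed_experiment_set_literal(self):
        u = parse_urn("urn:mavedb:00000055")
        assert u.experiment_set == 55
        assert u.level == "experiment_set"
        assert format_urn(u) == "urn:mavedb:00000055"

    def test_score_set_level(self):
        u = parse_urn("urn:mavedb:00000055-a-1")
        assert u.level == "score_set"
        assert (u.experiment_suffix, u.score_set_index) == ("a", 1)

    def test_variant_level_and_parents(self):
        u = parse_urn("urn:mavedb:00000055-a-1#7")
        assert u.level == "variant" and u.variant_index == 7
        assert format_urn(u.parent) == "urn:mavedb:00000055-a-1"
        assert u.extends(parse_urn("urn:mavedb:00000055"))
        assert not u.extends(parse_urn("urn:mavedb:00000056"))

    def test_temporary_namespace(self):
        u = parse_urn("tmp:mavedb:00000001-a")
        assert u.temporary and u.level == "experiment"
        assert format_urn(u) == "tmp:mavedb:00000001-a"

    @pytest.mark.parametrize("bad", [
        "urn:mavedb:55", "urn:mavedb:000000055", "urn:other:00000055",
        "urn:mavedb:00000055-A", "urn:mavedb:00000055-a-0",
        "urn:mavedb:00000055-1", "urn:mavedb:00000055-a-1#0",
        "urn:mavedb:00000055#1", "", "mavedb:00000055",
    ])
    def test_malformed(self, bad):
        with pytest.raises(MalformedUrn):
            parse_urn(bad)

    def test_invariants_on_construction(self):
        with pytest.raises(InvalidUrn):
            Urn(experiment_set=55, score_set_index=1)  # needs a suffix
        with pytest.raises(InvalidUrn):
            Urn(experiment_set=55, experiment_suffix="a",
                variant_index=1)  # needs a score-set index

    def test_round_trip_generated(self):
        rng = np.random.default_rng(42)
        letters = "abcdefghijklmnopqrstuvwxyz"
        for _ in range(500):
            depth = int(rng.integers(0, 4))
            u = Urn(
                experiment_set=int(rng.integers(1, 10**8)),
                experiment_suffix=(
                    "".join(rng.choice(list(letters),
                                       size=int(rng.integers(1, 3))))
                    if depth >= 1 else None),
                score_set_index=int(rng.integers(1, 50)) if depth >= 2 else None,
                variant_index=int(rng.integers(1, 10**6)) if depth >= 3 else None,
                temporary=bool(rng.random() < 0.2),
            )
            assert parse_urn(format_urn(u)) == u


class TestScoreTableValidation:
    def test_clean_protein_table(self, mwc_protein):
        t = ScoreTable.from_records(
            ["hgvs_pro", "score"],
            [["p.Met1Ala", "0.1"], ["p.Trp2Cys", "0.2"], ["p.Cys3del", "0.9"]],
        )
        assert validate_score_table(t, mwc_protein).valid

    def test_missing_score_column(self, mwc_protein):
        t = ScoreTable.from_records(["hgvs_pro"], [["p.Met1Ala"]])
        codes = [e.code for e in validate_score_table(t, mwc_protein).errors()]
        assert codes == ["MISSING_SCORE_COLUMN"]

    def test_duplicate_variant(self, mwc_protein):
        t = ScoreTable.from_records(
            ["hgvs_pro", "score"],
            [["p.Trp2Cys", "0.1"], ["p.Trp2Cys", "0.2"]],
        )
        codes = [e.code for e in validate_score_table(t, mwc_protein).errors()]
        assert codes == ["DUPLICATE_VARIANT"]

    def test_non_numeric_cell(self, mwc_protein):
        t = ScoreTable.from_records(
            ["hgvs_pro", "score"], [["p.Trp2Cys", "abc"]])
        codes = [e.code for e in validate_score_table(t, mwc_protein).errors()]
        assert codes == ["NON_NUMERIC"]

    def test_all_scores_missing_is_error(self, mwc_protein):
        t = ScoreTable.from_records(
            ["hgvs_pro", "score"], [["p.Trp2Cys", ""], ["p.Met1Ala", "NA"]])
        codes = [e.code for e in validate_score_table(t, mwc_protein).errors()]
        assert codes == ["ALL_SCORES_MISSING"]

    def test_individual_missing_scores_allowed(self, mwc_protein):
        t = ScoreTable.from_records(
            ["hgvs_pro", "score"], [["p.Trp2Cys", ""], ["p.Met1Ala", "0.5"]])
        assert validate_score_table(t, mwc_protein).valid

    def test_wrong_prefix_for_column(self, mwc_protein):
        t = ScoreTable.from_records(["hgvs_pro", "score"], [["c.1A>G", "0.1"]])
        codes = [e.code for e in validate_score_table(t, mwc_protein).errors()]
        assert codes == ["INCONSISTENT_PREFIX"]

    def test_no_variant_columns(self):
        t = ScoreTable.from_records(["score"], [["0.1"]])
        codes = [e.code for e in validate_score_table(t).errors()]
        assert codes == ["NO_VARIANT_COLUMNS"]


class TestCountConsistency:
    def _pair(self):
        scores = ScoreTable.from_records(
            ["hgvs_nt", "score"], [["n.1A>G", "0.5"], ["n.2T>C", "1.2"]])
        counts = CountTable.from_records(
            ["hgvs_nt", "count_pre", "count_post"],
            [["n.1A>G", "100", "50"], ["n.2T>C", "80", "90"]])
        return scores, counts

    def test_clean_pair(self):
        scores, counts = self._pair()
        assert validate_count_consistency(scores, counts).valid

    def test_extra_count_variant(self):
        scores, counts = self._pair()
        counts.df.loc[len(counts.df)] = ["n.3G>A", "10", "10"]
        codes = [e.code for e in
                 validate_count_consistency(scores, counts).errors()]
        assert codes == ["UNMATCHED_VARIANT"]

    def test_negative_count(self):
        scores, counts = self._pair()
        counts.df.at[0, "count_pre"] = "-3"
        codes = [e.code for e in
                 validate_count_consistency(scores, counts).errors()]
        assert codes == ["NEGATIVE_COUNT"]

    def test_row_with_no_data_at_all(self):
        scores, counts = self._pair()
        scores.df.at[1, "score"] = ""
        counts.df.at[1, "count_pre"] = ""
        counts.df.at[1, "count_post"] = "NA"
        codes = [e.code for e in
                 validate_count_consistency(scores, counts).errors()]
        assert codes == ["MISSING_DATA"]


class TestHierarchy:
    def test_meta_analysis_shape_validates(self):
        """Two assays combined into a function score: the canonical shape."""
        c = make_collection(GeneratorSpec(seed=3, n_variants=20),
                            n_experiments=2, with_meta_analysis=True)
        assert len(c.experiment_sets) == 1
        assert len(c.experiments) == 3  # 2 assays + the meta-analysis holder
        metas = [s for s in c.score_sets.values() if s.is_meta_analysis]
        assert len(metas) == 1 and len(metas[0].meta_analysis_sources) == 2
        assert validate_hierarchy(c).valid

    def test_cycle_detected(self):
        c = RecordCollection()
        c.add(ExperimentSetRecord("urn:mavedb:00000001"))
        c.add(ExperimentRecord("urn:mavedb:00000001-a", "urn:mavedb:00000001"))
        a = ScoreSetRecord("urn:mavedb:00000001-a-1", "urn:mavedb:00000001-a",
                           meta_analysis_sources=["urn:mavedb:00000001-a-2"])
        b = ScoreSetRecord("urn:mavedb:00000001-a-2", "urn:mavedb:00000001-a",
                           meta_analysis_sources=["urn:mavedb:00000001-a-1"])
        c.add(a), c.add(b)
        codes = {e.code for e in validate_hierarchy(c).errors()}
        assert "CYCLE" in codes

    def test_urn_mismatch(self):
        c = RecordCollection()
        c.add(ExperimentSetRecord("urn:mavedb:00000001"))
        c.add(ExperimentRecord("urn:mavedb:00000001-a", "urn:mavedb:00000001"))
        c.add(ExperimentSetRecord("urn:mavedb:00000002"))
        c.add(ScoreSetRecord("urn:mavedb:00000002-a-1",
                             "urn:mavedb:00000001-a"))
        codes = [e.code for e in validate_hierarchy(c).errors()]
        assert codes == ["URN_MISMATCH"]

    def test_orphans_detected(self):
        c = RecordCollection()
        c.add(ExperimentRecord("urn:mavedb:00000001-a", "urn:mavedb:00000001"))
        c.add(ScoreSetRecord("urn:mavedb:00000009-a-1",
                             "urn:mavedb:00000009-a"))
        codes = sorted(e.code for e in validate_hierarchy(c).errors())
        assert codes == ["ORPHAN_RECORD", "ORPHAN_RECORD"]

    def test_unresolved_meta_source(self):
        c = make_collection(GeneratorSpec(seed=4, n_variants=10),
                            n_experiments=1)
        ss = next(iter(c.score_sets.values()))
        ss.meta_analysis_sources.append("urn:mavedb:09999999-z-9")
        codes = [e.code for e in validate_hierarchy(c).errors()]
        assert codes == ["UNRESOLVED_SOURCE"]

    def test_multiple_primary_references(self):
        c = make_collection(GeneratorSpec(seed=5, n_variants=10),
                            n_experiments=1)
        ss = next(iter(c.score_sets.values()))
        ss.references = [
            Reference("1", "pubmed", is_primary=True),
            Reference("2", "biorxiv", is_primary=True),
        ]
        codes = [e.code for e in validate_hierarchy(c).errors()]
        assert codes == ["MULTIPLE_PRIMARY_REFERENCES"]

    def test_meta_attachment_preserves_source_tables(self):
        """Attaching a meta-analysis never rewrites source scores."""
        spec = GeneratorSpec(seed=6, n_variants=25)
        plain = make_collection(spec, n_experiments=2)
        with_meta = make_collection(spec, n_experiments=2,
                                    with_meta_analysis=True)
        for urn, ss in plain.score_sets.items():
            assert with_meta.score_sets[urn].scores == ss.scores
            assert with_meta.score_sets[urn].counts == ss.counts

    def test_validation_is_pure(self):
        c = make_collection(GeneratorSpec(seed=8, n_variants=15), 2, True)
        r1 = validate_hierarchy(c).to_dict()
        r2 = validate_hierarchy(c).to_dict()
        assert r1 == r2
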