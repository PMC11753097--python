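"""Histogram, effect-matrix and summary-stat behaviour."""

import math

import numpy as np
import pytest

from mavekit.errors import AlphabetMismatch, EmptyScores
from mavekit.grammar import EventKind, parse_variant
from mavekit.summarize import (
    NT_ROWS,
    PROTEIN_ROWS,
    effect_matrix,
    plot_effect_matrix,
    plot_histogram,
    score_histogram,
    summary_stats,
)
from mavekit.synth import GeneratorSpec, make_score_set, make_target
from mavekit.tables import ScoreTable


def _table(scores, column="hgvs_pro", variants=None):
    variants = variants or [f"p.Met{i + 1}Ala" for i in range(len(scores))]
    return ScoreTable.from_records(
        [column, "score"], list(zip(variants, scores)))


class TestHistogram:
    def test_equal_width_bins(self):
        h = score_histogram(_table(["0", "0", "1", "1"]), rule=[0.0, 0.5, 1.0])
        assert h.counts == [2, 2]

    def test_missing_conservation(self):
        h = score_histogram(_table(["1", "1", "1", "NA"]), rule=2)
        assert h.n_missing == 1 and sum(h.counts) == 3

    def test_all_missing_raises(self):
        with pytest.raises(EmptyScores):
            score_histogram(_table(["", "NA"]))

    def test_fd_matches_brute_force(self):
        """FD-rule counts equal an independent brute-force binning."""
        rng = np.random.default_rng(11)
        values = np.concatenate([rng.normal(0, 0.2, 400),
                                 rng.normal(1, 0.15, 600)])
        t = _table([repr(float(v)) for v in values],
                   variants=[f"p.Met{i + 1}Ala" for i in range(1000)])
        h = score_histogram(t)
        edges = np.asarray(h.bin_edges)
        brute = [0] * (len(edges) - 1)
        for v in values:  # half-open bins, last bin closed
            for b in range(len(brute)):
                last = b == len(brute) - 1
                if edges[b] <= v < edges[b + 1] or (last and v == edges[-1]):
                    brute[b] += 1
                    break
        assert h.counts == brute
        assert sum(h.counts) == 1000

    def test_iqr_zero_fallback(self):
        scores = ["0.5"] * 50 + ["1.5"]
        h = score_histogram(_table(scores,
                                   variants=[f"p.Met{i + 1}Ala"
                                             for i in range(51)]))
        assert len(h.counts) == 30  # equal-width fallback

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        scores = [repr(float(v)) for v in rng.normal(size=60)]
        variants = [f"p.Met{i + 1}Ala" for i in range(60)]
        h1 = score_histogram(_table(scores, variants=variants))
        order = rng.permutation(60)
        h2 = score_histogram(_table([scores[i] for i in order],
                                    variants=[variants[i] for i in order]))
        assert h1.counts == h2.counts and h1.bin_edges == h2.bin_edges


class TestEffectMatrix:
    def test_protein_example_cells(self, mwc_protein):
        t = ScoreTable.from_records(
            ["hgvs_pro", "score"],
            [["p.Met1Ala", "0.1"], ["p.Trp2Cys", "0.2"], ["p.Cys3del", "0.9"]])
        m = effect_matrix(t, mwc_protein)
        assert m.n_filled == 3 and m.n_excluded_multi == 0
        assert m.cells[m.row_labels.index("Ala"), 0] == 0.1
        assert m.cells[m.row_labels.index("Cys"), 1] == 0.2
        assert m.cells[m.row_labels.index("del"), 2] == 0.9

    def test_empty_table(self, mwc_protein):
        t = ScoreTable.from_records(["hgvs_pro", "score"], [])
        m = effect_matrix(t, mwc_protein)
        assert m.n_filled == 0 and m.n_excluded_multi == 0

    def test_multi_event_excluded(self, mwc_protein):
        t = ScoreTable.from_records(
            ["hgvs_pro", "score"], [["p.[Met1Ala;Trp2Cys]", "0.3"]])
        m = effect_matrix(t, mwc_protein)
        assert m.n_filled == 0 and m.n_excluded_multi == 1

    def test_row_alphabets(self, mwc_protein, atg_target):
        t = ScoreTable.from_records(["hgvs_pro", "score"], [["p.Met1Ala", "1"]])
        assert len(effect_matrix(t, mwc_protein).row_labels) == 22
        t = ScoreTable.from_records(["hgvs_nt", "score"], [["n.1A>G", "1"]])
        assert len(effect_matrix(t, atg_target).row_labels) == 5
        assert PROTEIN_ROWS[-1] == NT_ROWS[-1] == "del"

    def test_wt_mask_never_populated(self, mwc_coding):
        """Validated substitutions cannot land on the wild-type cell."""
        spec = GeneratorSpec(seed=21, n_variants=60, target_length=30,
                             multi_variant_fraction=0.0, missing_rate=0.0)
        target = make_target(spec)
        scores, _ = make_score_set(spec, target)
        m = effect_matrix(scores, target)
        for col, wt_row in enumerate(m.wt_mask):
            assert math.isnan(m.cells[wt_row, col])

    def test_alphabet_mismatch(self, atg_target, mwc_protein):
        t = ScoreTable.from_records(["hgvs_pro", "score"], [["p.Met1Ala", "1"]])
        with pytest.raises(AlphabetMismatch):
            effect_matrix(t, atg_target, level="protein")
        with pytest.raises(AlphabetMismatch):
            effect_matrix(t, mwc_protein, level="nucleotide")

    def test_conservation_over_generated_sets(self):
        """filled + excluded + missing-score singles == rows, every time."""
        for seed, kind in [(1, "coding"), (2, "non_coding"), (3, "protein")]:
            spec = GeneratorSpec(seed=seed, target_kind=kind,
                                 target_length=60 if kind != "protein" else 25,
                                 n_variants=80)
            target = make_target(spec)
            scores, _ = make_score_set(spec, target)
            m = effect_matrix(scores, target)
            col = scores.variant_columns[0]
            vals = scores.scores()
            missing_singles = 0
            for i in range(scores.n_rows):
                v = parse_variant(scores.df.at[i, col])
                ev = v.events[0]
                single = (not v.is_multi
                          and (ev.kind is EventKind.SUBSTITUTION
                               or (ev.kind is EventKind.DELETION
                                   and not ev.is_range)))
                if single and math.isnan(vals[i]):
                    missing_singles += 1
            assert m.n_filled + m.n_excluded_multi + missing_singles \
                == scores.n_rows


class TestSummaryStats:
    def test_basic(self):
        s = summary_stats(_table(["1", "2", "3"]))
        assert s["mean"] == 2 and s["median"] == 2

    def test_missing_excluded(self):
        s = summary_stats(_table(["5", "NA"]))
        assert s["n_variants"] == 2 and s["n_scored"] == 1 and s["mean"] == 5

    def test_agrees_with_brute_force(self):
        spec = GeneratorSpec(seed=31, n_variants=500, target_length=120)
        scores, _ = make_score_set(spec)
        s = summary_stats(scores)
        raw = [float(x) for x in scores.df["score"] if x not in ("", "NA")]
        assert s["mean"] == pytest.approx(sum(raw) / len(raw), abs=1e-12)
        assert s["median"] == pytest.approx(float(np.median(raw)), abs=1e-12)


class TestPlots:
    def test_figures_render(self, tmp_path, mwc_protein):
        t = ScoreTable.from_records(
            ["hgvs_pro", "score"],
            [["p.Met1Ala", "0.1"], ["p.Trp2Cys", "0.2"], ["p.Cys3del", "0.9"]])
        plot_histogram(score_histogram(t, rule=2), tmp_path / "h.png")
        plot_effect_matrix(effect_matrix(t, mwc_protein), tmp_path / "m.png")
        assert (tmp_path / "h.png").stat().st_size > 0
        assert (tmp_path / "m.png").stat().st_size > 0
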