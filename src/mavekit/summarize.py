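"""Automatic score-set summaries: histogram, effect matrix, summary stats.

The two standard at-a-glance views of a score set are a histogram of the
score distribution (MAVE score distributions are typically bimodal —
loss-of-function vs wild-type-like) and a variant-effect heatmap: one row
per possible substitution (plus a deletion row), one column per target
position.  Protein-level maps have 22 rows (20 amino acids + Ter + del);
nucleotide-level maps, used for non-coding targets, have 5 (A, C, G, T +
del).

Only single-event substitutions and single-position deletions occupy a
heatmap cell; multi-event variants, insertions and multi-position
deletions have no natural single cell and are tallied in
``n_excluded_multi`` (they still contribute to the histogram).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import AlphabetMismatch, EmptyScores, VariantSyntaxError
from .grammar import AA_CODES, EventKind, parse_variant
from .target_check import AA1_TO_3, TargetSequence
from .tables import ScoreTable

__all__ = [
    "EffectMatrix",
    "Histogram",
    "NT_ROWS",
    "PROTEIN_ROWS",
    "effect_matrix",
    "plot_effect_matrix",
    "plot_histogram",
    "score_histogram",
    "summary_stats",
]

#: fixed heatmap row orders; deletion row last, determinism over aesthetics
PROTEIN_ROWS = tuple(sorted(AA_CODES)) + ("del",)
NT_ROWS = ("A", "C", "G", "T", "del")


@dataclass
class Histogram:
    bin_edges: list[float]
    counts: list[int]
    n_missing: int

    def to_dict(self) -> dict:
        return {"bin_edges": self.bin_edges, "counts": self.counts,
                "n_missing": self.n_missing}


@dataclass
class EffectMatrix:
    row_labels: tuple[str, ...]
    col_positions: list[int]
    cells: np.ndarray  # float matrix, NaN = empty
    n_excluded_multi: int
    wt_mask: list[int]  # per-column row index of the target residue

    @property
    def n_filled(self) -> int:
        return int(np.sum(~np.isnan(self.cells)))

    def to_dict(self) -> dict:
        return {
            "row_labels": list(self.row_labels),
            "col_positions": self.col_positions,
            "cells": [[None if math.isnan(x) else x for x in row]
                      for row in self.cells.tolist()],
            "n_excluded_multi": self.n_excluded_multi,
            "wt_mask": self.wt_mask,
        }


def _fd_edges(values: np.ndarray) -> np.ndarray:
    """Freedman–Diaconis bin edges with a 30-equal-width fallback.

    The FD rule (bin width 2·IQR·n^(-1/3)) is robust for the bimodal
    distributions typical of MAVE scores; when the IQR is zero (heavily
    degenerate scores) it degenerates, so 30 equal-width bins are used
    instead.
    """
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    q75, q25 = np.percentile(values, [75, 25])
    iqr = q75 - q25
    if iqr <= 0:
        return np.linspace(lo, hi, 31)
    width = 2.0 * iqr / len(values) ** (1.0 / 3.0)
    n_bins = max(1, int(math.ceil((hi - lo) / width)))
    return np.linspace(lo, hi, n_bins + 1)


def score_histogram(t: ScoreTable, rule: str | int | list[float] = "fd") -> Histogram:
    """Bin the score column of a validated table.

    ``rule`` is ``"fd"`` (Freedman–Diaconis, the default), an integer
    number of equal-width bins, or an explicit edge list.  Counts plus
    ``n_missing`` always total the table's row count.  Raises
    :class:`EmptyScores` when no score is present at all.
    """
    scores = t.scores()
    present = scores[~np.isnan(scores)]
    n_missing = int(np.isnan(scores).sum())
    if present.size == 0:
        raise EmptyScores("cannot build a histogram: all scores are missing")
    if isinstance(rule, str):
        if rule != "fd":
            raise ValueError(f"unknown binning rule {rule!r}")
        edges = _fd_edges(present)
    elif isinstance(rule, int):
        lo, hi = float(present.min()), float(present.max())
        if lo == hi:
            lo, hi = lo - 0.5, hi + 0.5
        edges = np.linspace(lo, hi, rule + 1)
    else:
        edges = np.asarray(rule, dtype=float)
        if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("explicit bin edges must be strictly increasing")
    counts, edges = np.histogram(present, bins=edges)
    return Histogram(bin_edges=[float(e) for e in edges],
                     counts=[int(c) for c in counts],
                     n_missing=n_missing)


def _matrix_level(t: ScoreTable, target: TargetSequence) -> str:
    if target.kind == "protein" or target.is_coding:
        return "protein"
    return "nucleotide"


def effect_matrix(t: ScoreTable, target: TargetSequence,
                  level: str | None = None) -> EffectMatrix:
    """Build the variant-effect heatmap matrix for a validated table.

    ``level`` defaults to protein for protein/coding targets (reading
    ``hgvs_pro``) and nucleotide otherwise (reading ``hgvs_nt``).
    Requesting protein level for a target with no protein level, or a
    level whose variant column is absent, raises
    :class:`AlphabetMismatch`.
    """
    level = level or _matrix_level(t, target)
    if level == "protein":
        if target.kind == "nucleotide" and not target.is_coding:
            raise AlphabetMismatch(
                "protein-level matrix requested for a non-coding nucleotide target"
            )
        rows = PROTEIN_ROWS
        column = "hgvs_pro"
        wt_seq = target.protein()
        wt_rows = [rows.index(AA1_TO_3[c]) for c in wt_seq]
    elif level == "nucleotide":
        if target.kind != "nucleotide":
            raise AlphabetMismatch(
                "nucleotide-level matrix requested for a protein target"
            )
        rows = NT_ROWS
        column = "hgvs_nt"
        wt_seq = target.sequence
        wt_rows = [rows.index(c) for c in wt_seq]
    else:
        raise ValueError(f"unknown level {level!r}")
    if column not in t.columns:
        raise AlphabetMismatch(
            f"{level}-level matrix requires the {column} column"
        )

    L = len(wt_seq)
    cells = np.full((len(rows), L), np.nan)
    n_excluded = 0
    scores = t.scores()
    for i in range(t.n_rows):
        cell = t.df.at[i, column]
        if cell in ("", "NA"):
            n_excluded += 1
            continue
        try:
            v = parse_variant(cell)
        except VariantSyntaxError:
            n_excluded += 1
            continue
        ev = v.events[0]
        single_sub = (not v.is_multi and ev.kind is EventKind.SUBSTITUTION)
        single_del = (not v.is_multi and ev.kind is EventKind.DELETION
                      and not ev.is_range)
        if not (single_sub or single_del):
            n_excluded += 1
            continue
        pos = ev.start.index
        if pos > L:
            n_excluded += 1
            continue
        row = rows.index("del") if single_del else rows.index(ev.alt)
        if not math.isnan(scores[i]):
            cells[row, pos - 1] = scores[i]
    return EffectMatrix(row_labels=rows, col_positions=list(range(1, L + 1)),
                        cells=cells, n_excluded_multi=n_excluded,
                        wt_mask=wt_rows)


def summary_stats(t: ScoreTable) -> dict:
    """Landing-page statistics: row count, scored count, min/max/mean/median."""
    scores = t.scores()
    present = scores[~np.isnan(scores)]
    out = {"n_variants": int(t.n_rows), "n_scored": int(present.size)}
    if present.size:
        out.update(min=float(present.min()), max=float(present.max()),
                   mean=float(present.mean()), median=float(np.median(present)))
    else:
        out.update(min=None, max=None, mean=None, median=None)
    return out


def plot_histogram(h: Histogram, path: str, title: str = "Score distribution") -> None:
    """Render a histogram to an image file (static summary figure)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    edges = np.asarray(h.bin_edges)
    ax.bar(edges[:-1], h.counts, width=np.diff(edges), align="edge",
           color="#4878a8", edgecolor="white")
    ax.set_xlabel("score")
    ax.set_ylabel("variants")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_effect_matrix(m: EffectMatrix, path: str,
                       title: str = "Variant effect map") -> None:
    """Render the effect matrix as a heatmap; wild-type cells are dotted."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.25 * len(m.col_positions)), 0.3 * len(m.row_labels) + 1.5)
    )
    im = ax.imshow(m.cells, aspect="auto", cmap="RdBu_r", interpolation="nearest")
    ax.set_yticks(range(len(m.row_labels)), m.row_labels, fontsize=6)
    step = max(1, len(m.col_positions) // 25)
    ax.set_xticks(range(0, len(m.col_positions), step),
                  m.col_positions[::step], fontsize=6)
    for col, row in enumerate(m.wt_mask):
        ax.plot(col, row, ".", color="0.3", markersize=2)
    ax.set_xlabel("target position")
    fig.colorbar(im, ax=ax, label="score")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
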