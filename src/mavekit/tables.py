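"""Score and count tables with reserved variant-string columns.

A score table is a CSV (RFC 4180, UTF-8, mandatory header) whose reserved
columns are ``hgvs_nt``, ``hgvs_splice``, ``hgvs_pro`` (variant strings)
and ``score``; any number of additional numeric columns may be supplied
(standard errors, replicate scores, …).  A count table has the same variant
columns but carries nonnegative count columns instead of a score.

Cells equal to the empty string or ``NA`` (exactly) are missing.  Tables
are held as string-typed pandas DataFrames so that on-disk bytes survive a
read/write round-trip; numeric views are computed on demand.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import MaveKitError, VariantSyntaxError
from .grammar import Variant, parse_variant
from .report import ValidationReport
from .target_check import TargetSequence, validate_against_target

__all__ = [
    "CountTable",
    "MISSING_TOKENS",
    "RESERVED_VARIANT_COLUMNS",
    "ScoreTable",
    "validate_count_consistency",
    "validate_score_table",
]

RESERVED_VARIANT_COLUMNS = ("hgvs_nt", "hgvs_splice", "hgvs_pro")
MISSING_TOKENS = ("", "NA")

#: prefixes admissible in each variant column
_COLUMN_PREFIXES = {"hgvs_nt": {"g", "c", "n"}, "hgvs_splice": {"c", "n"},
                    "hgvs_pro": {"p"}}


def _is_missing(cell: str) -> bool:
    return cell in MISSING_TOKENS


def _to_float(cell: str) -> float:
    """Parse a numeric cell; missing → NaN; raises ValueError otherwise."""
    if _is_missing(cell):
        return math.nan
    return float(cell)


class _VariantTable:
    """Shared behaviour of score and count tables (string-cell DataFrame)."""

    def __init__(self, df: pd.DataFrame):
        if df.columns.duplicated().any():
            raise MaveKitError("table has duplicated column names")
        self.df = df.astype(str).reset_index(drop=True)
        # pandas renders genuine NaN cells as 'nan'; normalise to missing
        self.df = self.df.replace("nan", "")

    @classmethod
    def from_csv(cls, path: str | Path):
        df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[])
        return cls(df)

    @classmethod
    def from_records(cls, columns: list[str], rows: Iterable[Iterable]):
        data = [[("" if v is None or (isinstance(v, float) and math.isnan(v))
                  else str(v)) for v in row] for row in rows]
        return cls(pd.DataFrame(data, columns=columns, dtype=str))

    def to_csv(self, path: str | Path) -> None:
        # line terminator pinned for byte-stable output across platforms
        self.df.to_csv(path, index=False, lineterminator="\n")

    @property
    def columns(self) -> list[str]:
        return list(self.df.columns)

    @property
    def n_rows(self) -> int:
        return len(self.df)

    @property
    def variant_columns(self) -> list[str]:
        return [c for c in RESERVED_VARIANT_COLUMNS if c in self.df.columns]

    def variant_tuples(self) -> list[tuple]:
        """Per-row tuple over the reserved variant columns (identity key)."""
        cols = self.variant_columns
        return [tuple(row) for row in self.df[cols].itertuples(index=False, name=None)]

    def numeric(self, column: str) -> np.ndarray:
        """Float view of a column with NaN for missing; raises on bad cells."""
        return np.array([_to_float(c) for c in self.df[column]], dtype=float)

    def __eq__(self, other) -> bool:
        return isinstance(other, _VariantTable) and self.df.equals(other.df)

    def __len__(self) -> int:
        return self.n_rows


class ScoreTable(_VariantTable):
    """Per-variant functional scores plus optional extra numeric columns."""

    SCORE_COLUMN = "score"

    @property
    def extra_columns(self) -> list[str]:
        reserved = set(RESERVED_VARIANT_COLUMNS) | {self.SCORE_COLUMN}
        return [c for c in self.df.columns if c not in reserved]

    def scores(self) -> np.ndarray:
        return self.numeric(self.SCORE_COLUMN)


class CountTable(_VariantTable):
    """Per-variant sequencing (or similar) counts, e.g. pre/post selection."""

    @property
    def count_columns(self) -> list[str]:
        return [c for c in self.df.columns if c not in RESERVED_VARIANT_COLUMNS]


def _check_numeric_column(t: _VariantTable, col: str, report: ValidationReport,
                          nonnegative: bool = False,
                          negative_code: str = "NEGATIVE_COUNT") -> None:
    for i, cell in enumerate(t.df[col]):
        if _is_missing(cell):
            continue
        try:
            val = float(cell)
        except ValueError:
            report.error("NON_NUMERIC", f"cell {cell!r} is not numeric",
                         row=i, column=col)
            continue
        if nonnegative and val < 0:
            report.error(negative_code, f"count {cell!r} is negative",
                         row=i, column=col)


def _parse_row_variants(t: _VariantTable, row: int,
                        report: ValidationReport) -> dict[str, Variant]:
    """Parse every present variant cell in a row; findings for bad ones."""
    parsed: dict[str, Variant] = {}
    for col in t.variant_columns:
        cell = t.df.at[row, col]
        if _is_missing(cell):
            continue
        try:
            v = parse_variant(cell, splice_context=(col == "hgvs_splice"))
        except VariantSyntaxError as e:
            report.error("MALFORMED_VARIANT", f"{cell!r}: {e}", row=row, column=col)
            continue
        if v.prefix not in _COLUMN_PREFIXES[col]:
            report.error(
                "INCONSISTENT_PREFIX",
                f"prefix {v.prefix}. is not admissible in column {col}",
                row=row, column=col,
            )
            continue
        parsed[col] = v
    return parsed


def _check_duplicates(t: _VariantTable, report: ValidationReport) -> None:
    seen: dict[tuple, int] = {}
    for i, key in enumerate(t.variant_tuples()):
        if key in seen:
            report.error(
                "DUPLICATE_VARIANT",
                f"row repeats the variant tuple of row {seen[key]}",
                row=i,
            )
        else:
            seen[key] = i


def validate_score_table(t: ScoreTable, target: TargetSequence | None = None,
                         ) -> ValidationReport:
    """Validate a score table's schema, variant strings and target consistency.

    Findings cover: missing ``score`` column; absent variant columns;
    non-numeric cells in the score or extra columns; unparseable variant
    strings; column/prefix mismatches; target-inconsistent variants (when a
    target is given); duplicate variant tuples; and an entirely missing
    score column.  Individual missing score cells are allowed — variants
    may legitimately carry counts but no score after filtering.
    """
    report = ValidationReport()
    if not t.columns:
        raise MaveKitError("score table has no header")
    if not t.variant_columns:
        report.error("NO_VARIANT_COLUMNS",
                     "table defines none of hgvs_nt/hgvs_splice/hgvs_pro")
    has_score = ScoreTable.SCORE_COLUMN in t.columns
    if not has_score:
        report.error("MISSING_SCORE_COLUMN", 'required column "score" is absent')

    for row in range(t.n_rows):
        parsed = _parse_row_variants(t, row, report)
        if target is not None:
            for col, v in parsed.items():
                if col == "hgvs_splice":
                    # intronic bases are uncheckable without a genome
                    if any(e.start.offset or e.end.offset for e in v.events):
                        report.info(
                            "FORMAT_ONLY",
                            "splice variant validated for format only",
                            row=row, column=col,
                        )
                        continue
                report.extend(validate_against_target(v, target),
                              row=row, column=col)

    if has_score:
        _check_numeric_column(t, ScoreTable.SCORE_COLUMN, report)
        if t.n_rows and all(_is_missing(c) for c in t.df[ScoreTable.SCORE_COLUMN]):
            report.error("ALL_SCORES_MISSING",
                         'every cell of "score" is missing')
    for col in t.extra_columns:
        _check_numeric_column(t, col, report)
    _check_duplicates(t, report)
    return report


def validate_count_consistency(scores: ScoreTable,
                               counts: CountTable) -> ValidationReport:
    """Cross-validate a count table against its paired score table.

    Findings cover: count rows whose variant tuple is absent from the score
    table (and vice versa, code ``UNMATCHED_VARIANT``); negative counts;
    non-numeric count cells; and rows where the score is missing *and*
    every count is missing (code ``MISSING_DATA`` — such a row carries no
    information at all).
    """
    report = ValidationReport()
    if not scores.columns or not counts.columns:
        raise MaveKitError("tables must have headers")

    score_keys = dict(zip(scores.variant_tuples(), range(scores.n_rows)))
    count_keys = dict(zip(counts.variant_tuples(), range(counts.n_rows)))
    for key, i in count_keys.items():
        if key not in score_keys:
            report.error("UNMATCHED_VARIANT",
                         "count row has no matching score-table variant", row=i)
    for key, i in score_keys.items():
        if key not in count_keys:
            report.error("UNMATCHED_VARIANT",
                         "score row has no matching count-table variant", row=i)

    for col in counts.count_columns:
        _check_numeric_column(counts, col, report, nonnegative=True)

    if ScoreTable.SCORE_COLUMN in scores.columns:
        ccols = counts.count_columns
        for key, i in score_keys.items():
            if key not in count_keys:
                continue
            j = count_keys[key]
            if _is_missing(scores.df.at[i, ScoreTable.SCORE_COLUMN]) and all(
                _is_missing(counts.df.at[j, c]) for c in ccols
            ):
                report.error("MISSING_DATA",
                             "row has neither a score nor any count", row=i)
    return report
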