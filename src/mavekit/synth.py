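"""Deterministic synthetic targets, score sets and record collections.

Everything the other modules consume can be generated here with no
external data: target sequences, score/count tables whose variants are
read off the target (and therefore validate cleanly), and full record
collections including the canonical meta-analysis shape (one experiment
set, several experiments with one score set each, plus a meta-analysis
score set combining them into a single per-variant mean score).

Scores are drawn from a Gaussian mixture whose two default components
emulate the loss-of-function and wild-type-like classes that make real
MAVE score distributions bimodal (nonfunctional centred at 0, functional
centred at 1 — the common normalisation for growth-based selections).

Controlled defect seeding is the central testing device: a requested list
of ``(defect code, count)`` pairs is injected into otherwise-clean tables
such that downstream validation reports *exactly* those error findings.
All randomness flows through numpy's PCG64 generator seeded from the spec,
so identical specs are bit-reproducible across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import BadSpec, Exhausted
from .records import (
    ExperimentRecord,
    ExperimentSetRecord,
    RecordCollection,
    Reference,
    ScoreSetRecord,
)
from .tables import CountTable, ScoreTable
from .target_check import AA1_TO_3, TargetSequence, translate_dna
from .urn import Urn, format_urn

__all__ = [
    "DEFECT_CODES",
    "GeneratorSpec",
    "make_collection",
    "make_score_set",
    "make_target",
]

_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
)
_AA20 = "ARNDCQEGHILKMFPSTWYV"

#: Defect codes the generator can seed, with the validator that reports each:
#: REF_MISMATCH, OUT_OF_BOUNDS, MALFORMED_VARIANT, NON_NUMERIC,
#: DUPLICATE_VARIANT (score-table validation); NEGATIVE_COUNT,
#: UNMATCHED_VARIANT (count-consistency validation).
DEFECT_CODES = (
    "REF_MISMATCH",
    "OUT_OF_BOUNDS",
    "MALFORMED_VARIANT",
    "NON_NUMERIC",
    "DUPLICATE_VARIANT",
    "NEGATIVE_COUNT",
    "UNMATCHED_VARIANT",
)

_ROW_CONSUMING = {"REF_MISMATCH", "OUT_OF_BOUNDS", "MALFORMED_VARIANT",
                  "NON_NUMERIC", "DUPLICATE_VARIANT", "NEGATIVE_COUNT"}


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one synthetic dataset.

    ``target_kind`` is ``"coding"`` (nucleotide sequence read in frame,
    variants at the protein level), ``"non_coding"`` (nucleotide variants)
    or ``"protein"`` (a directly specified protein target).
    ``target_length`` is in nucleotides for nucleotide targets and
    residues for protein targets.  ``score_model`` gives the mixture
    components as (means, standard deviations, weights).
    """

    seed: int = 0
    target_kind: str = "coding"
    target_length: int = 90
    n_variants: int = 200
    multi_variant_fraction: float = 0.1
    deletion_fraction: float = 0.1
    component_means: tuple[float, ...] = (0.0, 1.0)
    component_sds: tuple[float, ...] = (0.2, 0.15)
    weights: tuple[float, ...] = (0.35, 0.65)
    missing_rate: float = 0.05
    defects: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if self.target_kind not in ("coding", "non_coding", "protein"):
            raise BadSpec(f"unknown target_kind {self.target_kind!r}")
        if self.target_length < 1:
            raise BadSpec("target_length must be positive")
        if self.target_kind == "coding" and self.target_length % 3:
            raise BadSpec("coding target length must be divisible by three")
        if self.n_variants < 1:
            raise BadSpec("n_variants must be positive")
        if not (0 <= self.multi_variant_fraction <= 1):
            raise BadSpec("multi_variant_fraction must be in [0, 1]")
        if not (0 <= self.deletion_fraction <= 1):
            raise BadSpec("deletion_fraction must be in [0, 1]")
        if not (0 <= self.missing_rate <= 1):
            raise BadSpec("missing_rate must be in [0, 1]")
        if not (len(self.component_means) == len(self.component_sds)
                == len(self.weights)) or not self.weights:
            raise BadSpec("mixture components must have equal nonzero length")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise BadSpec("mixture weights must sum to 1")
        if any(sd <= 0 for sd in self.component_sds):
            raise BadSpec("mixture standard deviations must be positive")
        for code, count in self.defects:
            if code not in DEFECT_CODES:
                raise BadSpec(f"unknown defect code {code!r}")
            if count < 0:
                raise BadSpec("defect counts must be nonnegative")


def _rng(spec: GeneratorSpec, stream: int) -> np.random.Generator:
    # independent streams per purpose so adding defects never perturbs scores
    return np.random.default_rng([spec.seed, stream])


def make_target(spec: GeneratorSpec) -> TargetSequence:
    """Generate the target sequence; deterministic for a fixed spec seed.

    Coding targets are built codon-by-codon from the 61 non-stop codons,
    so the translation has no internal stops.
    """
    rng = _rng(spec, 0)
    label = f"synthetic_{spec.target_kind}_{spec.seed}"
    if spec.target_kind == "coding":
        n_codons = spec.target_length // 3
        seq = "".join(rng.choice(_CODONS, size=n_codons))
        return TargetSequence(label, "nucleotide", seq, "coding")
    if spec.target_kind == "non_coding":
        seq = "".join(rng.choice(list("ACGT"), size=spec.target_length))
        return TargetSequence(label, "nucleotide", seq, "non_coding")
    seq = "".join(rng.choice(list(_AA20), size=spec.target_length))
    return TargetSequence(label, "protein", seq, "coding")


def _protein_single(rng, prot: str, used: set[str], deletion_fraction: float) -> str:
    for _ in range(1000):
        pos = int(rng.integers(1, len(prot) + 1))
        ref3 = AA1_TO_3[prot[pos - 1]]
        if rng.random() < deletion_fraction:
            s = f"p.{ref3}{pos}del"
        else:
            alt = AA1_TO_3[_AA20[int(rng.integers(len(_AA20)))]]
            if alt == ref3:
                continue
            s = f"p.{ref3}{pos}{alt}"
        if s not in used:
            return s
    raise Exhausted("cannot draw enough distinct protein variants")


def _protein_sub_event(rng, prot: str, pos: int) -> str:
    ref3 = AA1_TO_3[prot[pos - 1]]
    while True:
        alt = AA1_TO_3[_AA20[int(rng.integers(len(_AA20)))]]
        if alt != ref3:
            return f"{ref3}{pos}{alt}"


def _nt_single(rng, seq: str, used: set[str], deletion_fraction: float) -> str:
    for _ in range(1000):
        pos = int(rng.integers(1, len(seq) + 1))
        ref = seq[pos - 1]
        if rng.random() < deletion_fraction:
            s = f"n.{pos}del"
        else:
            alt = "ACGT"[int(rng.integers(4))]
            if alt == ref:
                continue
            s = f"n.{pos}{ref}>{alt}"
        if s not in used:
            return s
    raise Exhausted("cannot draw enough distinct nucleotide variants")


def _nt_sub_event(rng, seq: str, pos: int) -> str:
    ref = seq[pos - 1]
    while True:
        alt = "ACGT"[int(rng.integers(4))]
        if alt != ref:
            return f"{pos}{ref}>{alt}"


def _make_variants(spec: GeneratorSpec, target: TargetSequence) -> tuple[str, list[str]]:
    """Draw ``n_variants`` distinct valid variant strings off the target.

    Returns the table column name (``hgvs_pro`` or ``hgvs_nt``) and the
    variant strings.  Multi-variants are pairs of substitutions at
    distinct, ascending positions.
    """
    rng = _rng(spec, 1)
    protein_level = spec.target_kind in ("coding", "protein")
    seq = target.protein() if target.kind == "nucleotide" and protein_level \
        else target.sequence
    column = "hgvs_pro" if protein_level else "hgvs_nt"
    length = len(seq)
    if length < 2 and spec.multi_variant_fraction > 0:
        raise BadSpec("multi-variants need a target of length >= 2")

    used: set[str] = set()
    out: list[str] = []
    for _ in range(spec.n_variants):
        for _attempt in range(1000):
            if rng.random() < spec.multi_variant_fraction:
                p1, p2 = sorted(rng.choice(length, size=2, replace=False) + 1)
                if protein_level:
                    e1 = _protein_sub_event(rng, seq, int(p1))
                    e2 = _protein_sub_event(rng, seq, int(p2))
                    s = f"p.[{e1};{e2}]"
                else:
                    e1 = _nt_sub_event(rng, seq, int(p1))
                    e2 = _nt_sub_event(rng, seq, int(p2))
                    s = f"n.[{e1};{e2}]"
                if s in used:
                    continue
            elif protein_level:
                s = _protein_single(rng, seq, used, spec.deletion_fraction)
            else:
                s = _nt_single(rng, seq, used, spec.deletion_fraction)
            if s not in used:
                used.add(s)
                out.append(s)
                break
        else:
            raise Exhausted(
                f"cannot draw {spec.n_variants} distinct variants from a "
                f"length-{length} target"
            )
    return column, out


def _fmt(x: float) -> str:
    return repr(float(x))


def _draw_scores(spec: GeneratorSpec, rng: np.random.Generator, n: int) -> list[str]:
    comp = rng.choice(len(spec.weights), size=n, p=list(spec.weights))
    means = np.asarray(spec.component_means)[comp]
    sds = np.asarray(spec.component_sds)[comp]
    values = rng.normal(means, sds)
    missing = rng.random(n) < spec.missing_rate
    return ["" if m else _fmt(v) for v, m in zip(values, missing)]


def _single_sub_rows(column: str, variants: list[str]) -> list[int]:
    return [i for i, s in enumerate(variants)
            if "[" not in s and "del" not in s and "dup" not in s
            and "ins" not in s]


def _corrupt_ref(rng, s: str, column: str) -> str:
    """Rewrite a single-substitution string to state a wrong reference."""
    if column == "hgvs_pro":
        body = s[2:]
        ref3 = body[:3]
        rest = body[3:]
        alt3 = rest[len(rest) - 3:]
        while True:
            wrong = AA1_TO_3[_AA20[int(rng.integers(len(_AA20)))]]
            if wrong not in (ref3, alt3):
                return f"p.{wrong}{rest}"
    prefix, body = s[0], s[2:]
    ref = body[-3]
    alt = body[-1]
    while True:
        wrong = "ACGT"[int(rng.integers(4))]
        if wrong not in (ref, alt):
            return f"{prefix}.{body[:-3]}{wrong}>{alt}"


def _out_of_bounds_variant(column: str, target_len: int, salt: int) -> str:
    pos = target_len + 1 + salt
    if column == "hgvs_pro":
        return f"p.Ala{pos}Gly"
    return f"n.{pos}A>G"


def _apply_defects(spec: GeneratorSpec, target: TargetSequence, column: str,
                   scores_df: pd.DataFrame, counts_df: pd.DataFrame) -> tuple:
    """Inject the spec's defects; one downstream error finding per defect."""
    rng = _rng(spec, 3)
    expanded = [code for code, count in spec.defects for _ in range(count)]
    candidates = _single_sub_rows(column, list(scores_df[column]))
    need = sum(1 for c in expanded if c in _ROW_CONSUMING)
    if need > len(candidates):
        raise Exhausted(
            f"{need} row-consuming defects requested but only "
            f"{len(candidates)} clean single-substitution rows available"
        )
    rng.shuffle(candidates)
    pool = iter(candidates)

    protein_level = column == "hgvs_pro"
    tlen = len(target.protein()) if protein_level and target.kind == "nucleotide" \
        else len(target)
    dup_rows: list[int] = []
    extra_count_rows = 0
    for salt, code in enumerate(expanded):
        if code == "REF_MISMATCH":
            i = next(pool)
            bad = _corrupt_ref(rng, scores_df.at[i, column], column)
            scores_df.at[i, column] = bad
            counts_df.at[i, column] = bad
        elif code == "OUT_OF_BOUNDS":
            i = next(pool)
            bad = _out_of_bounds_variant(column, tlen, salt)
            scores_df.at[i, column] = bad
            counts_df.at[i, column] = bad
        elif code == "MALFORMED_VARIANT":
            i = next(pool)
            bad = f"p.Trp{i + 1}" if protein_level else f"n.{i + 1}A>"
            scores_df.at[i, column] = bad
            counts_df.at[i, column] = bad
        elif code == "NON_NUMERIC":
            i = next(pool)
            scores_df.at[i, "score"] = "not_a_number"
        elif code == "DUPLICATE_VARIANT":
            dup_rows.append(next(pool))
        elif code == "NEGATIVE_COUNT":
            i = next(pool)
            counts_df.at[i, "count_pre"] = "-3"
        elif code == "UNMATCHED_VARIANT":
            extra_count_rows += 1

    if dup_rows:
        scores_df = pd.concat(
            [scores_df, scores_df.loc[dup_rows]], ignore_index=True
        )
        counts_df = pd.concat(
            [counts_df, counts_df.loc[dup_rows]], ignore_index=True
        )
    for k in range(extra_count_rows):
        # a variant present in counts but absent from scores
        pos = tlen + 100 + k
        novel = f"p.Ala{pos}Gly" if protein_level else f"n.{pos}A>G"
        counts_df = pd.concat(
            [counts_df,
             pd.DataFrame([{column: novel, "count_pre": "10", "count_post": "5"}],
                          dtype=str)],
            ignore_index=True,
        ).fillna("")
    return scores_df, counts_df


def make_score_set(spec: GeneratorSpec,
                   target: TargetSequence | None = None,
                   score_stream: int = 2) -> tuple[ScoreTable, CountTable]:
    """Generate a paired score table and count table for a target.

    With an empty defect list the tables validate cleanly by construction;
    each seeded defect produces exactly one matching downstream error
    finding (see :data:`DEFECT_CODES`).  ``score_stream`` selects an
    independent score-noise stream so several score sets can share one
    variant list (as meta-analysis sources do).
    """
    if target is None:
        target = make_target(spec)
    column, variants = _make_variants(spec, target)
    rng = _rng(spec, score_stream)
    scores = _draw_scores(spec, rng, len(variants))
    se = [_fmt(abs(v)) for v in rng.normal(0.1, 0.02, size=len(variants))]
    pre = rng.integers(50, 2000, size=len(variants))
    post = rng.integers(10, 2000, size=len(variants))

    scores_df = pd.DataFrame(
        {column: variants, "score": scores, "se": se}, dtype=str
    )
    counts_df = pd.DataFrame(
        {column: variants,
         "count_pre": [str(int(x)) for x in pre],
         "count_post": [str(int(x)) for x in post]},
        dtype=str,
    )
    if spec.defects:
        scores_df, counts_df = _apply_defects(spec, target, column,
                                              scores_df, counts_df)
    return ScoreTable(scores_df), CountTable(counts_df)


def _suffix(i: int) -> str:
    """0 → a, 1 → b, …, 25 → z, 26 → aa, …"""
    out = ""
    i += 1
    while i:
        i, r = divmod(i - 1, 26)
        out = chr(ord("a") + r) + out
    return out


def _mean_scores(tables: list[ScoreTable]) -> list[str]:
    stacked = np.vstack([t.scores() for t in tables])
    out = []
    for col in stacked.T:
        present = col[~np.isnan(col)]
        out.append("" if present.size == 0 else _fmt(present.mean()))
    return out


def make_collection(spec: GeneratorSpec, n_experiments: int = 2,
                    with_meta_analysis: bool = False) -> RecordCollection:
    """Generate a full record collection.

    One experiment set contains ``n_experiments`` experiments with one
    score set each, all sharing a target and variant list but with
    independent score noise.  With ``with_meta_analysis`` an additional
    experiment holds a meta-analysis score set whose scores are the
    per-variant mean over all source score sets — combining the assays
    into a single function score while leaving the sources untouched.
    """
    if n_experiments < 1:
        raise BadSpec("n_experiments must be >= 1")
    target = make_target(spec)
    c = RecordCollection()
    es_urn = format_urn(Urn(experiment_set=spec.seed % 10**8 or 1))
    c.add(ExperimentSetRecord(urn=es_urn))
    ref = Reference(identifier="10.0000/synthetic", source="crossref_doi",
                    is_primary=True, journal_or_server="Synthetic Preprints",
                    authors=("Synthetic Author",), year=2024)

    source_urns: list[str] = []
    source_tables: list[ScoreTable] = []
    for i in range(n_experiments):
        exp_urn = f"{es_urn}-{_suffix(i)}"
        c.add(ExperimentRecord(
            urn=exp_urn, experiment_set=es_urn,
            title=f"Synthetic assay {i + 1}",
            short_description=f"Synthetic multiplexed assay {i + 1} on "
                              f"{target.label}",
            references=[ref],
        ))
        scores, counts = make_score_set(spec, target, score_stream=20 + i)
        ss_urn = f"{exp_urn}-1"
        c.add(ScoreSetRecord(
            urn=ss_urn, experiment=exp_urn,
            title=f"Synthetic scores {i + 1}",
            short_description="Scores from a synthetic selection",
            target=target, scores=scores, counts=counts, references=[ref],
        ))
        source_urns.append(ss_urn)
        source_tables.append(scores)

    if with_meta_analysis:
        exp_urn = f"{es_urn}-{_suffix(n_experiments)}"
        c.add(ExperimentRecord(
            urn=exp_urn, experiment_set=es_urn,
            title="Combined function score",
            short_description="Meta-analysis combining the synthetic assays",
        ))
        column = source_tables[0].variant_columns[0]
        meta_df = pd.DataFrame(
            {column: list(source_tables[0].df[column]),
             "score": _mean_scores(source_tables)},
            dtype=str,
        )
        c.add(ScoreSetRecord(
            urn=f"{exp_urn}-1", experiment=exp_urn,
            title="Function score",
            short_description="Per-variant mean of the source score sets",
            target=target, scores=ScoreTable(meta_df),
            meta_analysis_sources=source_urns,
        ))
    return c
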