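"""The hierarchical record model: experiment sets, experiments, score sets.

An *experiment set* groups related experiments (e.g. several assays on one
target from one study) and carries no data of its own.  An *experiment*
summarises one assay and groups the score sets derived from it.  A *score
set* holds the per-variant scores (and optional counts) against one target.
A *meta-analysis score set* is a score set derived by transforming or
combining existing score sets — imputation, cross-assay combination — and
is linked to its sources by accession without modifying them, so the
original scores stay preserved and discoverable.

Records reference publications: at most one *primary* reference (the paper
describing the data) plus any number of secondary references (methods,
reagents, software), drawn from PubMed, bioRxiv, medRxiv or Crossref DOIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .report import ValidationReport
from .tables import CountTable, ScoreTable
from .target_check import TargetSequence
from .urn import Urn, parse_urn

__all__ = [
    "ExperimentRecord",
    "ExperimentSetRecord",
    "RecordCollection",
    "Reference",
    "ScoreSetRecord",
    "validate_hierarchy",
]

_REFERENCE_SOURCES = ("pubmed", "biorxiv", "medrxiv", "crossref_doi")


@dataclass(frozen=True)
class Reference:
    """A publication or preprint attached to a record."""

    identifier: str
    source: str
    is_primary: bool = False
    journal_or_server: str | None = None
    authors: tuple[str, ...] = ()
    year: int | None = None

    def __post_init__(self) -> None:
        if self.source not in _REFERENCE_SOURCES:
            raise ValueError(f"unknown reference source {self.source!r}")

    def to_dict(self) -> dict:
        return {
            "identifier": self.identifier,
            "source": self.source,
            "is_primary": self.is_primary,
            "journal_or_server": self.journal_or_server,
            "authors": list(self.authors),
            "year": self.year,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Reference":
        return cls(
            identifier=d["identifier"],
            source=d["source"],
            is_primary=bool(d.get("is_primary", False)),
            journal_or_server=d.get("journal_or_server"),
            authors=tuple(d.get("authors") or ()),
            year=d.get("year"),
        )


@dataclass
class ExperimentSetRecord:
    urn: str

    def to_dict(self) -> dict:
        return {"urn": self.urn}


@dataclass
class ExperimentRecord:
    urn: str
    experiment_set: str
    title: str = ""
    short_description: str = ""
    abstract: str = ""
    methods: str = ""
    references: list[Reference] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "urn": self.urn,
            "experiment_set": self.experiment_set,
            "title": self.title,
            "short_description": self.short_description,
            "abstract": self.abstract,
            "methods": self.methods,
            "references": [r.to_dict() for r in self.references],
        }


@dataclass
class ScoreSetRecord:
    """A score set: scores (plus optional counts) against one target.

    ``target`` is either a local :class:`TargetSequence` or an accession
    string (transcript/genome anchored, resolved through a sequence
    lookup).  ``meta_analysis_sources`` is nonempty exactly when this
    record is a meta-analysis score set.
    """

    urn: str
    experiment: str
    title: str = ""
    short_description: str = ""
    abstract: str = ""
    methods: str = ""
    target: TargetSequence | str | None = None
    scores: ScoreTable | None = None
    counts: CountTable | None = None
    references: list[Reference] = field(default_factory=list)
    meta_analysis_sources: list[str] = field(default_factory=list)

    @property
    def is_meta_analysis(self) -> bool:
        return bool(self.meta_analysis_sources)

    def to_dict(self) -> dict:
        if isinstance(self.target, TargetSequence):
            target = {
                "label": self.target.label,
                "kind": self.target.kind,
                "sequence": self.target.sequence,
                "category": self.target.category,
            }
        else:
            target = self.target
        return {
            "urn": self.urn,
            "experiment": self.experiment,
            "title": self.title,
            "short_description": self.short_description,
            "abstract": self.abstract,
            "methods": self.methods,
            "target": target,
            "references": [r.to_dict() for r in self.references],
            "meta_analysis_sources": list(self.meta_analysis_sources),
            "has_counts": self.counts is not None,
        }


@dataclass
class RecordCollection:
    """All records of one database snapshot, keyed by accession."""

    experiment_sets: dict[str, ExperimentSetRecord] = field(default_factory=dict)
    experiments: dict[str, ExperimentRecord] = field(default_factory=dict)
    score_sets: dict[str, ScoreSetRecord] = field(default_factory=dict)

    def add(self, record) -> None:
        if isinstance(record, ExperimentSetRecord):
            self.experiment_sets[record.urn] = record
        elif isinstance(record, ExperimentRecord):
            self.experiments[record.urn] = record
        elif isinstance(record, ScoreSetRecord):
            self.score_sets[record.urn] = record
        else:
            raise TypeError(f"cannot add {type(record).__name__} to a collection")

    def canonical_form(self) -> dict:
        """Nested plain-data view (tables as cell lists) for equality checks."""
        def table(t):
            return None if t is None else {"columns": t.columns,
                                           "rows": [list(r) for r in
                                                    t.df.itertuples(index=False, name=None)]}
        return {
            "experiment_sets": {u: r.to_dict() for u, r in
                                sorted(self.experiment_sets.items())},
            "experiments": {u: r.to_dict() for u, r in
                            sorted(self.experiments.items())},
            "score_sets": {
                u: {**r.to_dict(), "scores": table(r.scores),
                    "counts": table(r.counts)}
                for u, r in sorted(self.score_sets.items())
            },
        }


def _check_references(urn: str, refs: list[Reference],
                      report: ValidationReport) -> None:
    if sum(r.is_primary for r in refs) > 1:
        report.error("MULTIPLE_PRIMARY_REFERENCES",
                     f"{urn} declares more than one primary reference")


def validate_hierarchy(c: RecordCollection) -> ValidationReport:
    """Validate parent links, accession structure and meta-analysis edges.

    Error findings: unparseable or wrong-level accessions
    (``MALFORMED_URN``); children whose stated parent is absent
    (``ORPHAN_RECORD``); children whose accession does not extend their
    stated parent's (``URN_MISMATCH``); meta-analysis sources that do not
    resolve to a score set (``UNRESOLVED_SOURCE``); cycles in the
    meta-analysis graph (``CYCLE``); multiple primary references.
    Info findings: meta-analyses spanning experiment sets; experiments
    grouping several score sets (legitimate for reanalyses, surfaced as a
    reminder of the one-experiment-per-assay convention).
    """
    report = ValidationReport()

    def parsed(urn: str, expected_level: str) -> Urn | None:
        try:
            u = parse_urn(urn)
        except Exception as e:
            report.error("MALFORMED_URN", f"{urn!r}: {e}")
            return None
        if u.level != expected_level:
            report.error("MALFORMED_URN",
                         f"{urn} is a {u.level}-level accession, expected "
                         f"{expected_level}")
            return None
        return u

    for urn in c.experiment_sets:
        parsed(urn, "experiment_set")

    for urn, exp in c.experiments.items():
        u = parsed(urn, "experiment")
        if exp.experiment_set not in c.experiment_sets:
            report.error("ORPHAN_RECORD",
                         f"experiment {urn} references missing experiment set "
                         f"{exp.experiment_set}")
        elif u is not None:
            try:
                pu = parse_urn(exp.experiment_set)
            except Exception:
                pu = None
            if pu is None or not u.extends(pu):
                report.error("URN_MISMATCH",
                             f"experiment accession {urn} does not extend its "
                             f"experiment set {exp.experiment_set}")
        _check_references(urn, exp.references, report)

    per_experiment: dict[str, int] = {}
    for urn, ss in c.score_sets.items():
        u = parsed(urn, "score_set")
        per_experiment[ss.experiment] = per_experiment.get(ss.experiment, 0) + 1
        if ss.experiment not in c.experiments:
            report.error("ORPHAN_RECORD",
                         f"score set {urn} references missing experiment "
                         f"{ss.experiment}")
        elif u is not None:
            try:
                pu = parse_urn(ss.experiment)
            except Exception:
                pu = None
            if pu is None or not u.extends(pu):
                report.error("URN_MISMATCH",
                             f"score-set accession {urn} does not extend its "
                             f"experiment {ss.experiment}")
        _check_references(urn, ss.references, report)

        for src in ss.meta_analysis_sources:
            if src not in c.score_sets:
                report.error("UNRESOLVED_SOURCE",
                             f"meta-analysis {urn} sources missing score set {src}")

    for exp_urn, n in per_experiment.items():
        if n > 1 and exp_urn in c.experiments:
            report.info("MULTIPLE_SCORE_SETS",
                        f"experiment {exp_urn} groups {n} score sets; the "
                        "convention is one experiment per assay")

    graph = nx.DiGraph()
    graph.add_nodes_from(c.score_sets)
    for urn, ss in c.score_sets.items():
        for src in ss.meta_analysis_sources:
            if src in c.score_sets:
                graph.add_edge(urn, src)
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        report.error("CYCLE",
                     "meta-analysis sources form a cycle: "
                     + " -> ".join(e[0] for e in cycle))

    for urn, ss in c.score_sets.items():
        if not ss.is_meta_analysis:
            continue
        try:
            own_set = parse_urn(urn).experiment_set
            spans = {parse_urn(s).experiment_set
                     for s in ss.meta_analysis_sources if s in c.score_sets}
        except Exception:
            continue
        if spans - {own_set}:
            report.info("CROSS_EXPERIMENT_SET_META",
                        f"meta-analysis {urn} sources score sets from other "
                        "experiment sets")
    return report
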