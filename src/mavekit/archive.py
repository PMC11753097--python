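"""Bulk-release archive: one JSON metadata file plus a directory of CSVs.

The archive layout mirrors the bulk-download format of a database
snapshot: a single ``metadata.json`` carrying the structured metadata for
every experiment set, experiment and score set, and a ``tables/``
directory with one scores CSV (and optionally one counts CSV) per score
set.  File contents are byte-stable: records are sorted by accession, JSON
keys are sorted, numbers use shortest round-trip decimals, and CSV line
endings are pinned — writing the same collection twice produces
bit-identical files.

The JSON layout is defined by the schema document shipped at
``mavekit/schemas/archive.schema.json``; ``version_tag`` labels the
snapshot (e.g. a release date) so users can cite a specific version.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import CorruptArchive, InvalidCollection
from .records import (
    ExperimentRecord,
    ExperimentSetRecord,
    RecordCollection,
    Reference,
    ScoreSetRecord,
    validate_hierarchy,
)
from .report import ValidationReport
from .tables import CountTable, ScoreTable
from .target_check import TargetSequence

__all__ = ["ArchiveManifest", "ArchiveReadResult", "read_archive", "write_archive"]

METADATA_FILENAME = "metadata.json"
TABLES_DIRNAME = "tables"
FORMAT_VERSION = 1


@dataclass
class ArchiveManifest:
    metadata_path: Path
    table_paths: dict[str, dict[str, Path]] = field(default_factory=dict)
    version_tag: str = ""


@dataclass
class ArchiveReadResult:
    """A loaded collection plus per-table findings from the read."""

    collection: RecordCollection
    report: ValidationReport
    manifest: ArchiveManifest


def _safe_name(urn: str) -> str:
    """Accession → filesystem-safe stem (``:`` and ``#`` are unsafe)."""
    return urn.replace(":", "-").replace("#", "-")


def _metadata_document(c: RecordCollection, version_tag: str) -> dict:
    return {
        "format_version": FORMAT_VERSION,
        "version_tag": version_tag,
        "experiment_sets": [c.experiment_sets[u].to_dict()
                            for u in sorted(c.experiment_sets)],
        "experiments": [c.experiments[u].to_dict()
                        for u in sorted(c.experiments)],
        "score_sets": [c.score_sets[u].to_dict()
                       for u in sorted(c.score_sets)],
    }


def write_archive(c: RecordCollection, dest: str | Path,
                  version_tag: str = "") -> ArchiveManifest:
    """Write a collection as a bulk-release archive directory.

    Requires the collection to pass hierarchy validation with no errors
    (:class:`InvalidCollection` otherwise).  Returns the manifest of
    written paths.
    """
    hierarchy = validate_hierarchy(c)
    if not hierarchy.valid:
        codes = sorted({f.code for f in hierarchy.errors()})
        raise InvalidCollection(
            f"collection fails hierarchy validation ({', '.join(codes)}); "
            "fix the findings before exporting"
        )
    dest = Path(dest)
    dest.mkdir(parents=True, exist_ok=True)
    tables_dir = dest / TABLES_DIRNAME
    tables_dir.mkdir(exist_ok=True)

    metadata_path = dest / METADATA_FILENAME
    doc = _metadata_document(c, version_tag)
    metadata_path.write_text(
        json.dumps(doc, sort_keys=True, indent=2, ensure_ascii=False) + "\n",
        encoding="utf-8",
    )

    manifest = ArchiveManifest(metadata_path=metadata_path,
                               version_tag=version_tag)
    for urn in sorted(c.score_sets):
        ss = c.score_sets[urn]
        stem = _safe_name(urn)
        paths: dict[str, Path] = {}
        if ss.scores is not None:
            paths["scores"] = tables_dir / f"{stem}.scores.csv"
            ss.scores.to_csv(paths["scores"])
        if ss.counts is not None:
            paths["counts"] = tables_dir / f"{stem}.counts.csv"
            ss.counts.to_csv(paths["counts"])
        manifest.table_paths[urn] = paths
    return manifest


def _target_from_dict(d) -> TargetSequence | str | None:
    if d is None or isinstance(d, str):
        return d
    if not isinstance(d, dict):
        raise CorruptArchive(f"unreadable target entry: {d!r}")
    return TargetSequence(label=d["label"], kind=d["kind"],
                          sequence=d["sequence"],
                          category=d.get("category", "other"))


def _require(d: dict, keys: list[str], where: str) -> None:
    missing = [k for k in keys if k not in d]
    if missing:
        raise CorruptArchive(f"{where} is missing required keys {missing}")


def read_archive(src: str | Path) -> ArchiveReadResult:
    """Load a bulk-release archive directory.

    ``read_archive(write_archive(c))`` reproduces ``c`` up to canonical
    formatting.  Missing or unreadable table files produce
    ``MISSING_TABLE``/``UNREADABLE_TABLE`` findings in the result's report
    rather than exceptions; an absent or unparseable ``metadata.json``
    raises :class:`CorruptArchive`.
    """
    src = Path(src)
    metadata_path = src / METADATA_FILENAME
    if not metadata_path.is_file():
        raise CorruptArchive(f"no {METADATA_FILENAME} in {src}")
    try:
        doc = json.loads(metadata_path.read_text(encoding="utf-8"))
    except (OSError, json.JSONDecodeError) as e:
        raise CorruptArchive(f"unreadable {METADATA_FILENAME}: {e}") from e
    if not isinstance(doc, dict):
        raise CorruptArchive("archive metadata must be a JSON object")
    _require(doc, ["experiment_sets", "experiments", "score_sets"],
             METADATA_FILENAME)

    report = ValidationReport()
    collection = RecordCollection()
    for d in doc["experiment_sets"]:
        _require(d, ["urn"], "experiment set entry")
        collection.add(ExperimentSetRecord(urn=d["urn"]))
    for d in doc["experiments"]:
        _require(d, ["urn", "experiment_set"], "experiment entry")
        collection.add(ExperimentRecord(
            urn=d["urn"], experiment_set=d["experiment_set"],
            title=d.get("title", ""),
            short_description=d.get("short_description", ""),
            abstract=d.get("abstract", ""), methods=d.get("methods", ""),
            references=[Reference.from_dict(r) for r in d.get("references", [])],
        ))

    tables_dir = src / TABLES_DIRNAME
    manifest = ArchiveManifest(metadata_path=metadata_path,
                               version_tag=doc.get("version_tag", ""))
    for d in doc["score_sets"]:
        _require(d, ["urn", "experiment"], "score set entry")
        urn = d["urn"]
        stem = _safe_name(urn)
        scores_path = tables_dir / f"{stem}.scores.csv"
        counts_path = tables_dir / f"{stem}.counts.csv"
        scores = counts = None
        paths: dict[str, Path] = {}
        if scores_path.is_file():
            try:
                scores = ScoreTable.from_csv(scores_path)
                paths["scores"] = scores_path
            except Exception as e:
                report.error("UNREADABLE_TABLE",
                             f"scores CSV for {urn} unreadable: {e}")
        else:
            report.error("MISSING_TABLE", f"scores CSV for {urn} is missing")
        if d.get("has_counts"):
            if counts_path.is_file():
                try:
                    counts = CountTable.from_csv(counts_path)
                    paths["counts"] = counts_path
                except Exception as e:
                    report.error("UNREADABLE_TABLE",
                                 f"counts CSV for {urn} unreadable: {e}")
            else:
                report.error("MISSING_TABLE",
                             f"counts CSV for {urn} is missing")
        manifest.table_paths[urn] = paths
        collection.add(ScoreSetRecord(
            urn=urn, experiment=d["experiment"],
            title=d.get("title", ""),
            short_description=d.get("short_description", ""),
            abstract=d.get("abstract", ""), methods=d.get("methods", ""),
            target=_target_from_dict(d.get("target")),
            scores=scores, counts=counts,
            references=[Reference.from_dict(r) for r in d.get("references", [])],
            meta_analysis_sources=list(d.get("meta_analysis_sources", [])),
        ))
    return ArchiveReadResult(collection=collection, report=report,
                             manifest=manifest)
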