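"""Validation findings and reports shared by all validators.

Validators in this package never raise on bad *data* — they collect
findings, so that a score table with twelve problems produces one report
listing twelve findings rather than dying on the first.  Exceptions are
reserved for violated preconditions (missing header, unreadable file).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum


class Severity(str, Enum):
    ERROR = "error"
    WARNING = "warning"
    INFO = "info"


@dataclass(frozen=True)
class Finding:
    """One validation observation.

    ``locus`` is a 1-based target position where applicable; ``row`` a
    0-based data-row index into the source table; ``column`` the table
    column involved.
    """

    code: str
    severity: Severity
    message: str
    locus: int | None = None
    row: int | None = None
    column: str | None = None

    def to_dict(self) -> dict:
        d = {"code": self.code, "severity": self.severity.value, "message": self.message}
        for k in ("locus", "row", "column"):
            v = getattr(self, k)
            if v is not None:
                d[k] = v
        return d

    @property
    def sort_key(self) -> tuple:
        order = {Severity.ERROR: 0, Severity.WARNING: 1, Severity.INFO: 2}
        return (order[self.severity], self.row if self.row is not None else -1,
                self.code, self.locus if self.locus is not None else -1)


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        """True iff the report contains no error-severity findings."""
        return not any(f.severity is Severity.ERROR for f in self.findings)

    def error(self, code: str, message: str, **kw) -> None:
        self.findings.append(Finding(code, Severity.ERROR, message, **kw))

    def warning(self, code: str, message: str, **kw) -> None:
        self.findings.append(Finding(code, Severity.WARNING, message, **kw))

    def info(self, code: str, message: str, **kw) -> None:
        self.findings.append(Finding(code, Severity.INFO, message, **kw))

    def extend(self, other: "ValidationReport", row: int | None = None,
               column: str | None = None) -> None:
        """Merge another report, optionally stamping row/column context."""
        for f in other.findings:
            if row is not None or column is not None:
                f = Finding(f.code, f.severity, f.message, locus=f.locus,
                            row=f.row if f.row is not None else row,
                            column=f.column if f.column is not None else column)
            self.findings.append(f)

    def errors(self) -> list[Finding]:
        return [f for f in self.findings if f.severity is Severity.ERROR]

    def sorted_findings(self) -> list[Finding]:
        return sorted(self.findings, key=lambda f: f.sort_key)

    def to_dict(self) -> dict:
        return {
            "valid": self.valid,
            "findings": [f.to_dict() for f in self.sorted_findings()],
        }
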