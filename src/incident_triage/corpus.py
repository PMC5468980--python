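"""Incident report records and corpus serialization (JSONL / CSV)."""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

#: Columns used by both the JSONL and CSV corpus formats.
CORPUS_FIELDS = ("report_id", "narrative", "incident_type", "severity", "source")


@dataclass(frozen=True)
class IncidentReport:
    """One free-text incident report with optional gold labels.

    At least one of ``incident_type`` / ``severity`` must be present for a
    labeled corpus; unlabeled reports are permitted only at prediction time.
    """

    report_id: str
    narrative: str
    incident_type: Optional[str] = None
    severity: Optional[str] = None
    source: str = field(default="unknown")

    def word_count(self) -> int:
        return len(self.narrative.split())


def write_jsonl(reports: Iterable[IncidentReport], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for r in reports:
            fh.write(
                json.dumps(
                    {
                        "report_id": r.report_id,
                        "narrative": r.narrative,
                        "incident_type": r.incident_type,
                        "severity": r.severity,
                        "source": r.source,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_jsonl(path: str | Path) -> list[IncidentReport]:
    reports = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            d = json.loads(line)
            reports.append(
                IncidentReport(
                    report_id=str(d["report_id"]),
                    narrative=d["narrative"],
                    incident_type=d.get("incident_type"),
                    severity=d.get("severity"),
                    source=d.get("source", "unknown"),
                )
            )
    return reports


def write_csv(reports: Iterable[IncidentReport], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(CORPUS_FIELDS))
        writer.writeheader()
        for r in reports:
            writer.writerow(
                {
                    "report_id": r.report_id,
                    "narrative": r.narrative,
                    "incident_type": r.incident_type or "",
                    "severity": r.severity or "",
                    "source": r.source,
                }
            )


def read_csv(path: str | Path) -> list[IncidentReport]:
    reports = []
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            reports.append(
                IncidentReport(
                    report_id=str(row["report_id"]),
                    narrative=row["narrative"],
                    incident_type=row.get("incident_type") or None,
                    severity=row.get("severity") or None,
                    source=row.get("source") or "unknown",
                )
            )
    return reports


def read_corpus(path: str | Path) -> list[IncidentReport]:
    """Read a corpus, dispatching on file extension (.jsonl/.json vs .csv)."""
    path = Path(path)
    if path.suffix.lower() in (".jsonl", ".json"):
        return read_jsonl(path)
    if path.suffix.lower() == ".csv":
        return read_csv(path)
    raise ValueError(f"unsupported corpus format: {path.suffix!r} (use .jsonl or .csv)")
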