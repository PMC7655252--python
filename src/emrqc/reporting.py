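"""Batch ingest, assessment orchestration, and conformance reports.

Reads record batches from delimited (CSV) or JSON-lines files, runs the
integrity, coding, and star-rating assessments under one rule configuration,
and writes the result as a lossless JSON report or a human-readable Markdown
summary. Per-row parse problems are warnings, never silent drops: every
input row is accounted for as an assessed record and/or a warning.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

from . import __version__
from .model import (
    OutpatientRecord,
    ParseWarning,
    RuleConfig,
    parse_record,
)
from .registry import CodeSetRegistry, rule_config_to_dict
from .scoring import (
    BatchAssessment,
    EmptyBatchError,
    RecordAssessment,
    assess_coding,
    assess_mandatory,
    coding_score,
    display_score,
    integrity_score,
    total_score,
)
from .star import batch_star, rate_record


@dataclass
class RecordDetail:
    """Per-record line of a conformance report."""

    record_id: str | None
    missing_count: int
    noncompliant_count: int
    star_level: int
    failed_mandatory: list[str] = field(default_factory=list)
    failed_coding: list[str] = field(default_factory=list)


@dataclass
class ConformanceReport:
    """A complete batch conformance report.

    Scores are carried at full precision; the displayed integers are their
    half-up roundings. ``batch_star`` is a reconstruction (count-weighted
    mean star level) and is always accompanied by the full distribution.
    """

    institution: str
    timestamp: str
    config_fingerprint: str
    n: int
    k_integrity: int
    k_coding: int
    integrity_score: float
    coding_score: float
    total_score: float
    star_counts: dict[int, int]
    batch_star: int
    records: list[RecordDetail]
    warnings: list[str] = field(default_factory=list)
    tool_version: str = __version__

    @property
    def displayed_scores(self) -> dict[str, int]:
        return {
            "integrity": display_score(self.integrity_score),
            "coding": display_score(self.coding_score),
            "total": display_score(self.total_score),
        }


def config_fingerprint(config: RuleConfig) -> str:
    """Content hash of the resolved configuration (traceability of reports)."""
    canonical = json.dumps(rule_config_to_dict(config), sort_keys=True)
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Reading record batches

def read_records(
    path: str | Path,
    format: str = "csv",
    field_mapping: Mapping[str, str] | None = None,
    delimiter: str = "|",
    csv_delimiter: str = ",",
) -> tuple[list[OutpatientRecord], list[ParseWarning]]:
    """Read a batch of records from a CSV or JSON-lines file.

    ``delimiter`` splits multi-valued cells; ``csv_delimiter`` separates CSV
    columns. Row order is preserved; per-row issues become warnings while
    the row still yields a record (with the offending field missing).
    Duplicate record ids are kept, with a warning.
    """
    path = Path(path)
    if format == "csv":
        rows: Iterable[Mapping[str, Any]] = _iter_csv(path, csv_delimiter)
    elif format in ("jsonl", "json_lines"):
        rows = _iter_jsonl(path)
    else:
        raise ValueError(f"unknown record format {format!r} (expected csv or jsonl)")

    records: list[OutpatientRecord] = []
    warnings: list[ParseWarning] = []
    seen_ids: set[str] = set()
    for row in rows:
        record, row_warnings = parse_record(row, field_mapping, delimiter)
        records.append(record)
        warnings.extend(row_warnings)
        if record.record_id is not None:
            if record.record_id in seen_ids:
                warnings.append(
                    ParseWarning(record.record_id, "duplicate record_id (kept)")
                )
            seen_ids.add(record.record_id)
    return records, warnings


def _iter_csv(path: Path, csv_delimiter: str):
    with path.open(encoding="utf-8", newline="") as handle:
        yield from csv.DictReader(handle, delimiter=csv_delimiter)


def _iter_jsonl(path: Path):
    with path.open(encoding="utf-8") as handle:
        for line_no, line in enumerate(handle, 1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{line_no}: invalid JSON: {exc}") from exc
            if not isinstance(obj, dict):
                raise ValueError(f"{path}:{line_no}: each line must be an object")
            yield obj


# ---------------------------------------------------------------------------
# Batch assessment

def assess_record(
    record: OutpatientRecord, config: RuleConfig, registry: CodeSetRegistry
) -> RecordAssessment:
    """Run integrity, coding, and star assessment on one record."""
    x, mandatory_flags = assess_mandatory(record, config.mandatory_rules)
    y, coding_flags = assess_coding(record, config.coding_rules, registry)
    assessment = RecordAssessment(
        record_id=record.record_id,
        missing_count=x,
        noncompliant_count=y,
        mandatory_flags=mandatory_flags,
        coding_flags=coding_flags,
    )
    rate_record(assessment, config.star_scheme, config)
    return assessment


def summarize_assessments(
    assessments: Sequence[RecordAssessment], config: RuleConfig
) -> BatchAssessment:
    """Aggregate per-record assessments into batch scores and star counts."""
    if not assessments:
        raise EmptyBatchError("cannot assess an empty batch")
    si = integrity_score([a.missing_count for a in assessments], config.k_integrity)
    sc = coding_score([a.noncompliant_count for a in assessments], config.k_coding)
    st = total_score(si, sc, config.weights)
    counts = {level: 0 for level in range(config.star_scheme.max_level + 1)}
    for a in assessments:
        counts[a.star_level] += 1
    return BatchAssessment(
        n=len(assessments),
        k_integrity=config.k_integrity,
        k_coding=config.k_coding,
        integrity_score=si,
        coding_score=sc,
        total_score=st,
        star_counts=counts,
        batch_star=batch_star(counts),
    )


def assess_batch(
    records: Sequence[OutpatientRecord],
    config: RuleConfig,
    registry: CodeSetRegistry,
    institution: str = "",
    warnings: Sequence[ParseWarning] = (),
    timestamp: str | None = None,
) -> ConformanceReport:
    """Assess a batch of records and assemble the full conformance report."""
    registry.validate_config(config)
    if not records:
        raise EmptyBatchError("cannot assess an empty batch")
    assessments = [assess_record(r, config, registry) for r in records]
    batch = summarize_assessments(assessments, config)
    details = [
        RecordDetail(
            record_id=a.record_id,
            missing_count=a.missing_count,
            noncompliant_count=a.noncompliant_count,
            star_level=a.star_level,
            failed_mandatory=[
                rule.item_name
                for rule, ok in zip(config.mandatory_rules, a.mandatory_flags)
                if not ok
            ],
            failed_coding=[
                rule.item_name
                for rule, ok in zip(config.coding_rules, a.coding_flags)
                if not ok
            ],
        )
        for a in assessments
    ]
    if timestamp is None:
        timestamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
    return ConformanceReport(
        institution=institution,
        timestamp=timestamp,
        config_fingerprint=config_fingerprint(config),
        n=batch.n,
        k_integrity=batch.k_integrity,
        k_coding=batch.k_coding,
        integrity_score=batch.integrity_score,
        coding_score=batch.coding_score,
        total_score=batch.total_score,
        star_counts=batch.star_counts,
        batch_star=batch.batch_star,
        records=details,
        warnings=[f"{w.record_id or '?'}: {w.message}" for w in warnings],
    )


# ---------------------------------------------------------------------------
# Writing and reloading reports

def report_to_dict(report: ConformanceReport) -> dict[str, Any]:
    """JSON-ready form of a report (lossless, full-precision scores)."""
    return {
        "metadata": {
            "institution": report.institution,
            "timestamp": report.timestamp,
            "config_fingerprint": report.config_fingerprint,
            "tool_version": report.tool_version,
        },
        "n": report.n,
        "k_integrity": report.k_integrity,
        "k_coding": report.k_coding,
        "scores": {
            "integrity": {
                "value": report.integrity_score,
                "display": display_score(report.integrity_score),
            },
            "coding": {
                "value": report.coding_score,
                "display": display_score(report.coding_score),
            },
            "total": {
                "value": report.total_score,
                "display": display_score(report.total_score),
            },
        },
        "star_counts": {
            str(level): report.star_counts[level]
            for level in sorted(report.star_counts, reverse=True)
        },
        "batch_star": report.batch_star,
        "batch_star_method": "count-weighted mean, half-up (reconstruction)",
        "records": [dataclasses.asdict(d) for d in report.records],
        "warnings": list(report.warnings),
    }


def report_from_dict(doc: Mapping[str, Any]) -> ConformanceReport:
    """Rebuild a report from its JSON form."""
    meta = doc["metadata"]
    return ConformanceReport(
        institution=meta["institution"],
        timestamp=meta["timestamp"],
        config_fingerprint=meta["config_fingerprint"],
        tool_version=meta["tool_version"],
        n=doc["n"],
        k_integrity=doc["k_integrity"],
        k_coding=doc["k_coding"],
        integrity_score=doc["scores"]["integrity"]["value"],
        coding_score=doc["scores"]["coding"]["value"],
        total_score=doc["scores"]["total"]["value"],
        star_counts={int(k): v for k, v in doc["star_counts"].items()},
        batch_star=doc["batch_star"],
        records=[RecordDetail(**d) for d in doc["records"]],
        warnings=list(doc["warnings"]),
    )


def write_report(
    report: ConformanceReport, path: str | Path, format: str = "json"
) -> Path:
    """Write a report as JSON (lossless) or Markdown (displayed integers)."""
    path = Path(path)
    if format == "json":
        path.write_text(
            json.dumps(report_to_dict(report), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
    elif format == "markdown":
        path.write_text(render_markdown(report), encoding="utf-8")
    else:
        raise ValueError(f"unknown report format {format!r}")
    return path


def load_report(path: str | Path) -> ConformanceReport:
    return report_from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def render_markdown(report: ConformanceReport) -> str:
    """Human-readable report: displayed scores and the star table (5 -> 0)."""
    shown = report.displayed_scores
    lines = [
        "# EMR standard-compliance report",
        "",
        f"- Institution: {report.institution or '(unspecified)'}",
        f"- Generated: {report.timestamp}",
        f"- Records assessed: {report.n}",
        f"- Rule configuration: `{report.config_fingerprint}`",
        "",
        "## Scores",
        "",
        "| Assessment | Score (points) |",
        "| --- | --- |",
        f"| Integrity (S_i) | {shown['integrity']} |",
        f"| Coding standard (S_c) | {shown['coding']} |",
        f"| Total (S_t) | {shown['total']} |",
        "",
        "## Star rating",
        "",
        "| Star level | Records |",
        "| --- | --- |",
    ]
    for level in sorted(report.star_counts, reverse=True):
        lines.append(f"| {level}-star | {report.star_counts[level]} |")
    lines += [
        f"| Total | {report.n} |",
        "",
        f"Batch star level (count-weighted mean, reconstruction): "
        f"{report.batch_star}",
    ]
    if report.warnings:
        lines += ["", "## Warnings", ""]
        lines += [f"- {w}" for w in report.warnings]
    return "\n".join(lines) + "\n"
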