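"""Conversion module: raw app records → archetype-conformant coded extracts.

This is the app-side half of the pipeline: it takes the uncoded records a
patient mobile app stores (side-effect reports with Spanish literals, daily
activity tracking) and produces EN/ISO 13606 extract documents whose finding
and severity elements carry SNOMED CT coded values, resolved through the
mapping config.

Privacy contract: extracts carry only the pseudonymous app-side patient ID
(``subject_id = app_patient_id``).  The study-side identifier lives in the
:class:`PatientLink` table, which is consumed exclusively by the repository
at ingestion time — communication is unidirectional and no hospital or
study identifier ever enters an extract.

Batching is daily and per record: one extract per (patient, date, record
type), with a deterministic extract_id computed as a content hash so that
re-sent extracts deduplicate downstream.  Per-record conversion failures
are collected and reported without aborting the batch, matching an
unattended daily send.
"""

from __future__ import annotations

import csv
import datetime as _dt
import hashlib
import json
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .reference_model import (
    CodedValue,
    DateValue,
    ExtractDocument,
    QuantityValue,
    TextValue,
    build_entry,
)
from .terminology import MappingConfig, UnmappedTermError, resolve

__all__ = [
    "SideEffectRecord",
    "ActivityRecord",
    "AppRecord",
    "PatientLink",
    "ConversionError",
    "BatchFailure",
    "BatchResult",
    "convert_side_effect",
    "convert_activity",
    "convert_record",
    "batch_daily",
    "load_records",
    "dump_records",
    "load_links",
    "dump_links",
    "extract_filename",
]


class ConversionError(ValueError):
    """A record cannot be converted into a valid extract."""


class _Record(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    app_patient_id: str
    date: _dt.date

    @field_validator("app_patient_id")
    @classmethod
    def _nonempty(cls, v: str) -> str:
        if not v:
            raise ValueError("app_patient_id must be non-empty")
        return v

    @field_validator("date", mode="before")
    @classmethod
    def _parse_date(cls, v):
        if isinstance(v, str):
            return _dt.date.fromisoformat(v)
        return v


class SideEffectRecord(_Record):
    """One side-effect report: date, finding literal, optional free-text
    value, severity literal (all literals uncoded, typically Spanish)."""

    finding_label: str
    value_text: Optional[str] = None
    severity_label: str

    @field_validator("finding_label")
    @classmethod
    def _finding_nonempty(cls, v: str) -> str:
        if not v:
            raise ValueError("finding_label must be non-empty")
        return v


class ActivityRecord(_Record):
    """One day of activity tracking: steps, calories, duration."""

    steps: float
    calories: float
    duration: float

    @model_validator(mode="after")
    def _nonneg(self) -> "ActivityRecord":
        for f in ("steps", "calories", "duration"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        return self


AppRecord = Union[SideEffectRecord, ActivityRecord]


class PatientLink(BaseModel):
    """App-side pseudonymous ID ↔ study-side ID, bijective within a table."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    app_patient_id: str
    study_id: str


def _archetype_of(record: AppRecord) -> str:
    return "side_effect" if isinstance(record, SideEffectRecord) else "daily_activity"


def _extract_id(subject_id: str, archetype_id: str, date: _dt.date, payload) -> str:
    blob = json.dumps(
        [subject_id, archetype_id, date.isoformat(), payload],
        sort_keys=True,
        ensure_ascii=False,
    )
    return hashlib.sha256(blob.encode("utf-8")).hexdigest()[:32]


def _midnight_utc(date: _dt.date) -> _dt.datetime:
    return _dt.datetime(date.year, date.month, date.day, tzinfo=_dt.timezone.utc)


def convert_side_effect(
    record: SideEffectRecord, mapping: MappingConfig
) -> ExtractDocument:
    """Convert one side-effect report into a one-entry coded extract.

    Finding and severity literals are resolved to SNOMED CT coded values;
    an unmapped literal propagates :class:`UnmappedTermError` — the module
    never emits uncoded data.  The optional free-text ``value`` element is
    omitted when the record has none.
    """
    finding = resolve(mapping, "findings", record.finding_label)
    severity = resolve(mapping, "severities", record.severity_label)
    values = {
        "date": DateValue(value=record.date),
        "finding": CodedValue(
            concept_id=finding.concept_id,
            scheme_uri=mapping.scheme_uri,
            display=finding.display,
        ),
        "severity": CodedValue(
            concept_id=severity.concept_id,
            scheme_uri=mapping.scheme_uri,
            display=severity.display,
        ),
    }
    if record.value_text is not None:
        values["value"] = TextValue(value=record.value_text)
    entry = build_entry("side_effect", values)
    payload = [
        finding.concept_id,
        severity.concept_id,
        record.value_text,
    ]
    return ExtractDocument(
        extract_id=_extract_id(record.app_patient_id, "side_effect", record.date, payload),
        subject_id=record.app_patient_id,
        time_created=_midnight_utc(record.date),
        entries=(entry,),
    )


def convert_activity(record: ActivityRecord) -> ExtractDocument:
    """Convert one daily-activity record into a one-entry extract with
    quantity elements in steps / kcal / min."""
    values = {
        "date": DateValue(value=record.date),
        "steps": QuantityValue(magnitude=record.steps, unit="steps"),
        "calories": QuantityValue(magnitude=record.calories, unit="kcal"),
        "duration": QuantityValue(magnitude=record.duration, unit="min"),
    }
    entry = build_entry("daily_activity", values)
    payload = [record.steps, record.calories, record.duration]
    return ExtractDocument(
        extract_id=_extract_id(
            record.app_patient_id, "daily_activity", record.date, payload
        ),
        subject_id=record.app_patient_id,
        time_created=_midnight_utc(record.date),
        entries=(entry,),
    )


def convert_record(record: AppRecord, mapping: MappingConfig) -> ExtractDocument:
    if isinstance(record, SideEffectRecord):
        return convert_side_effect(record, mapping)
    return convert_activity(record)


class BatchFailure(BaseModel):
    model_config = ConfigDict(frozen=True)

    index: int
    app_patient_id: str
    date: _dt.date
    record_type: str
    reason: str


class BatchResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    extracts: tuple[ExtractDocument, ...] = ()
    failures: tuple[BatchFailure, ...] = ()

    def report(self) -> dict:
        return {
            "n_records": len(self.extracts) + len(self.failures),
            "n_converted": len(self.extracts),
            "n_failed": len(self.failures),
            "failures": [
                {
                    "index": f.index,
                    "app_patient_id": f.app_patient_id,
                    "date": f.date.isoformat(),
                    "record_type": f.record_type,
                    "reason": f.reason,
                }
                for f in self.failures
            ],
        }


def batch_daily(records: Iterable[AppRecord], mapping: MappingConfig) -> BatchResult:
    """Convert a batch of app records, one extract per record.

    Output order is deterministic: (patient, date, archetype).  Failures
    (unmapped literals, invalid values) are collected per record and never
    abort the batch.
    """
    extracts: list[ExtractDocument] = []
    failures: list[BatchFailure] = []
    seen_activity_days: set[tuple[str, _dt.date]] = set()
    for i, record in enumerate(records):
        try:
            if isinstance(record, ActivityRecord):
                key = (record.app_patient_id, record.date)
                if key in seen_activity_days:
                    raise ConversionError(
                        f"second activity record for patient {record.app_patient_id} "
                        f"on {record.date} (at most one per day)"
                    )
                seen_activity_days.add(key)
            extracts.append(convert_record(record, mapping))
        except (UnmappedTermError, ConversionError, ValueError) as exc:
            failures.append(
                BatchFailure(
                    index=i,
                    app_patient_id=record.app_patient_id,
                    date=record.date,
                    record_type=_archetype_of(record),
                    reason=str(exc),
                )
            )
    extracts.sort(
        key=lambda x: (x.subject_id, x.time_created, x.entries[0].archetype_id)
    )
    return BatchResult(extracts=tuple(extracts), failures=tuple(failures))


def extract_filename(extract: ExtractDocument) -> str:
    """Canonical file name ``<subject>_<archetype>_<date>.xml``."""
    entry = extract.entries[0]
    date = ""
    for el in entry.elements:
        if isinstance(el.value, DateValue):
            date = el.value.value.isoformat()
            break
    return f"{extract.subject_id}_{entry.archetype_id}_{date}.xml"


# --- record / link table I/O -------------------------------------------------

_RECORD_TYPES = {"side_effect": SideEffectRecord, "daily_activity": ActivityRecord}


def _record_to_dict(record: AppRecord) -> dict:
    d = record.model_dump(mode="json")
    d["type"] = _archetype_of(record)
    return d


def dump_records(records: Sequence[AppRecord], path: Union[str, Path]) -> None:
    """Write records as a JSON array with a ``type`` discriminator."""
    Path(path).write_text(
        json.dumps([_record_to_dict(r) for r in records], ensure_ascii=False, indent=1)
        + "\n",
        encoding="utf-8",
    )


def load_records(path: Union[str, Path]) -> list[AppRecord]:
    """Read records from a JSON array or line-delimited JSON file."""
    text = Path(path).read_text(encoding="utf-8").strip()
    if text.startswith("["):
        items = json.loads(text)
    else:
        items = [json.loads(line) for line in text.splitlines() if line.strip()]
    records: list[AppRecord] = []
    for i, item in enumerate(items):
        kind = item.pop("type", None)
        cls = _RECORD_TYPES.get(kind)
        if cls is None:
            raise ConversionError(f"record[{i}]: unknown or missing type {kind!r}")
        try:
            records.append(cls.model_validate(item))
        except ValueError as exc:
            raise ConversionError(f"record[{i}]: {exc}") from exc
    return records


def dump_links(links: Sequence[PatientLink], path: Union[str, Path]) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["app_patient_id", "study_id"])
        for link in links:
            writer.writerow([link.app_patient_id, link.study_id])


def load_links(path: Union[str, Path]) -> list[PatientLink]:
    """Read the app↔study link table (CSV); enforces bijectivity."""
    with Path(path).open(newline="", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    links = [PatientLink.model_validate(row) for row in rows]
    app_ids = [l.app_patient_id for l in links]
    study_ids = [l.study_id for l in links]
    if len(set(app_ids)) != len(app_ids) or len(set(study_ids)) != len(study_ids):
        raise ConversionError(f"{path}: link table is not bijective")
    return links
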