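"""Typed domain model for one sample's NGS quality-control dossier.

A :class:`QcRecord` groups the ~30 quality data elements of a clinical
NGS run into four workflow-stage blocks (sample preparation, library
preparation split into DNA extraction and library construction,
sequencing, data processing).  Construction coerces types (dates, ints,
floats, enum codes) but deliberately does *not* enforce value ranges:
out-of-range measurements are real-world data and are surfaced by
:func:`validate_record` as issues, never swallowed at parse time.
"""

from __future__ import annotations

import csv
import datetime as _dt
import math
from typing import Any, Dict, Iterable, List, Mapping, Optional

from pydantic import BaseModel, ConfigDict, field_validator

from .elements import (
    ALL_PATHS,
    BY_PATH,
    ELEMENTS,
    Kind,
    ReadDirection,
    SequencingType,
    SpecimenType,
)


class QcModelError(ValueError):
    """Unknown element path or uncoercible value."""


class _Block(BaseModel):
    model_config = ConfigDict(validate_assignment=True, extra="forbid")


class SamplePreparation(_Block):
    sequencing_type: Optional[SequencingType] = None
    target_gene: Optional[List[str]] = None
    specimen_type: Optional[SpecimenType] = None
    sampling_date: Optional[_dt.date] = None

    @field_validator("target_gene", mode="before")
    @classmethod
    def _split_genes(cls, v):
        if isinstance(v, str):
            return [g for g in v.split(";") if g]
        return v


class DnaExtraction(_Block):
    extraction_kit: Optional[str] = None
    od_260_280: Optional[float] = None
    od_260_230: Optional[float] = None
    dna_median_size: Optional[float] = None


class LibraryConstruction(_Block):
    input_amount: Optional[float] = None
    input_size: Optional[float] = None
    construction_kit: Optional[str] = None


class SequencingRun(_Block):
    instrument: Optional[str] = None
    read_length: Optional[int] = None
    direction: Optional[ReadDirection] = None
    running_mode: Optional[str] = None
    error_rate: Optional[float] = None
    pct_q30: Optional[float] = None


class DataProcessing(_Block):
    total_reads: Optional[int] = None
    mean_coverage: Optional[float] = None
    uniformity: Optional[float] = None
    on_target_rate: Optional[float] = None
    q30: Optional[float] = None
    pr_score: Optional[float] = None
    mapping_algorithm: Optional[str] = None
    alignment_software: Optional[str] = None
    variant_calling_software: Optional[str] = None
    quality_score: Optional[float] = None
    allelic_read_percentage: Optional[float] = None
    germline_filter_criteria: Optional[str] = None
    reference_database: Optional[str] = None


_STAGE_MODELS = {
    "sample_prep": SamplePreparation,
    "dna_extraction": DnaExtraction,
    "library": LibraryConstruction,
    "sequencing": SequencingRun,
    "processing": DataProcessing,
}


class QcRecord(_Block):
    """One sample's complete QC dossier."""

    record_id: str
    patient_ref: Optional[str] = None
    sample_prep: SamplePreparation = SamplePreparation()
    dna_extraction: DnaExtraction = DnaExtraction()
    library: LibraryConstruction = LibraryConstruction()
    sequencing: SequencingRun = SequencingRun()
    processing: DataProcessing = DataProcessing()

    def get(self, path: str):
        """Value at a dotted element path, or ``None`` if absent."""
        if path in ("record_id", "patient_ref"):
            return getattr(self, path)
        if path not in BY_PATH:
            raise QcModelError(f"unknown element path: {path!r}")
        stage, name = path.split(".", 1)
        return getattr(getattr(self, stage), name)


class Issue(BaseModel):
    model_config = ConfigDict(frozen=True)
    path: str
    severity: str  # "error" | "warning"
    code: str
    message: str


class ValidationReport(BaseModel):
    issues: List[Issue] = []

    @property
    def ok(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    @property
    def errors(self) -> List[Issue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> List[Issue]:
        return [i for i in self.issues if i.severity == "warning"]

    def sorted(self) -> "ValidationReport":
        return ValidationReport(
            issues=sorted(self.issues, key=lambda i: (i.path, i.code)))


def make_record(field_map: Mapping[str, Any]) -> QcRecord:
    """Build a :class:`QcRecord` from a flat dotted-path → value mapping.

    Unknown paths are rejected; values are coerced to their semantic
    types ("85.0" → 85.0, "2021-03-02" → date).  Empty strings and None
    mean "absent" and are skipped, never stored as sentinels.
    """
    staged: Dict[str, Dict[str, Any]] = {s: {} for s in _STAGE_MODELS}
    top: Dict[str, Any] = {}
    for path, value in field_map.items():
        if value is None or (isinstance(value, str) and value == ""):
            continue
        if isinstance(value, float) and math.isnan(value):
            continue
        if path in ("record_id", "patient_ref"):
            top[path] = str(value)
            continue
        el = BY_PATH.get(path)
        if el is None:
            raise QcModelError(f"unknown element path: {path!r}")
        staged[el.stage][el.field_name] = value
    if "record_id" not in top or not top["record_id"]:
        raise QcModelError("record_id is required and must be non-empty")
    try:
        return QcRecord(
            record_id=top["record_id"],
            patient_ref=top.get("patient_ref"),
            **{s: _STAGE_MODELS[s](**fields) for s, fields in staged.items()},
        )
    except QcModelError:
        raise
    except Exception as exc:  # pydantic coercion failure → name the path
        raise QcModelError(f"uncoercible value: {exc}") from exc


def flatten_record(record: QcRecord) -> Dict[str, Any]:
    """Flat mapping of dotted path → scalar; inverse of :func:`make_record`.

    Absent fields are omitted.  Dates render as ISO-8601 strings, enum
    codes as their string value and gene lists as ``;``-joined strings so
    every value fits a CSV cell.
    """
    out: Dict[str, Any] = {"record_id": record.record_id}
    if record.patient_ref is not None:
        out["patient_ref"] = record.patient_ref
    for el in ELEMENTS:
        v = record.get(el.path)
        if v is None:
            continue
        if el.kind == Kind.DATE:
            v = v.isoformat()
        elif el.kind == Kind.CODE:
            v = v.value
        elif el.kind == Kind.GENE_LIST:
            v = ";".join(v)
        out[el.path] = v
    return out


def validate_record(record: QcRecord) -> ValidationReport:
    """Check every value-range invariant; report, never raise.

    Out-of-range values are errors; data elements that are simply absent
    produce "missing" warnings (no element is mandated beyond the record
    identifier and the stage blocks themselves).  Issues are ordered
    deterministically by element path.
    """
    issues: List[Issue] = []
    if not record.record_id:
        issues.append(Issue(path="record_id", severity="error", code="empty-id",
                            message="record_id must be non-empty"))
    for el in ELEMENTS:
        v = record.get(el.path)
        if v is None:
            issues.append(Issue(
                path=el.path, severity="warning", code="missing",
                message=f"{el.path} is absent"))
            continue
        if el.range is not None and el.numeric and not el.range.check(float(v)):
            issues.append(Issue(
                path=el.path, severity="error", code="out-of-range",
                message=f"{el.path}={v!r} outside {el.range.describe()}"
                        + (f" {el.unit}" if el.unit else "")))
    return ValidationReport(issues=issues).sorted()


# ---------------------------------------------------------------------------
# CSV ingest/export: one row per record, header = dotted paths, empty cell
# = absent field (RFC 4180 via the csv module).

def records_to_csv(records: Iterable[QcRecord], path) -> int:
    rows = [flatten_record(r) for r in records]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(ALL_PATHS))
        writer.writeheader()
        for row in rows:
            writer.writerow(row)
    return len(rows)


def records_from_csv(path) -> List[QcRecord]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        return [make_record({k: v for k, v in row.items() if v not in (None, "")})
                for row in reader]
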